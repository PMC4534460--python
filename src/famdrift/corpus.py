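"""Reading, validating and grouping the case-marking database.

The database is a flat CSV with one row per grammatical subsystem of one
language.  Each subsystem (e.g. ``perfective+main`` in Hindi) is one
evolutionary trial: a binary record of whether an ergative marker is present
in that corner of the grammar.  Languages with no attested subsystem split
carry a single ``whole-language`` trial.  Every language is keyed to two
genealogical classifications (autotyp and glottolog) and to one of five
geo-linguistic areas used to control for contact effects.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

AREAS = (
    "Africa",
    "Eurasia",
    "Pacific",
    "South America",
    "Rest of the Americas",
)

WHOLE_LANGUAGE = "whole-language"

#: canonical column names; a column_map may translate foreign headers to these
CANONICAL_COLUMNS = (
    "language",
    "autotyp_family",
    "glottolog_family",
    "area",
    "subsystem",
    "ergative",
)

TAXONOMIES = ("autotyp", "glottolog")

DEFAULT_LARGE_CUTOFF = 5


class SchemaError(ValueError):
    """A required column is missing from the database file."""


class ValidationError(ValueError):
    """A record violates the database invariants."""


@dataclass(frozen=True)
class SubsystemRecord:
    """One evolutionary trial: a grammatical subsystem with a binary value."""

    language_id: str
    family_autotyp: str
    family_glottolog: str
    area: str
    subsystem_label: str
    ergative: int

    def family(self, taxonomy: str) -> str:
        if taxonomy == "autotyp":
            return self.family_autotyp
        if taxonomy == "glottolog":
            return self.family_glottolog
        raise ValueError(f"unknown taxonomy {taxonomy!r}")


@dataclass
class FamilyDataset:
    """All trials of one family within one taxonomy and one area.

    This is the unit of bias testing: ``trials`` holds one binary value per
    subsystem record, ``languages`` the distinct member languages.  A family
    is *large* when it has at least ``cutoff`` member languages (default 5).
    """

    family_id: str
    taxonomy: str
    area: str
    languages: list[str]
    trials: list[int]
    trials_by_language: dict[str, list[int]] = field(default_factory=dict)
    cutoff: int = DEFAULT_LARGE_CUTOFF

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_languages(self) -> int:
        return len(self.languages)

    @property
    def is_large(self) -> bool:
        return self.n_languages >= self.cutoff

    @property
    def is_variable(self) -> bool:
        """True when both trait values occur among the trials."""
        return 0 < sum(self.trials) < self.n_trials


@dataclass
class FamilyTree:
    """A rooted family tree with binary (possibly polymorphic) tip states.

    ``tip_states`` maps language id to 0, 1 or the string ``"polymorphic"``
    for languages whose subsystems disagree.  Unit branch lengths are the
    default, mirroring the convention that each node in a genealogical
    classification is one opportunity for type change.
    """

    tree: dendropy.Tree
    tip_states: dict[str, object]

    POLYMORPHIC = "polymorphic"

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def _normalize_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def read_database(
    path: str | Path,
    strict: bool = True,
    column_map: Mapping[str, str] | None = None,
) -> list[SubsystemRecord]:
    """Read and validate a case-marking database CSV.

    Parameters
    ----------
    path
        CSV file with the canonical columns (or columns translatable to them
        via ``column_map``): language, autotyp_family, glottolog_family,
        area, subsystem, ergative.  Extra columns are preserved upstream but
        ignored here.
    strict
        If True, an unknown area value raises :class:`ValidationError`; if
        False the record is skipped with a warning.
    column_map
        Optional mapping from the file's column names to canonical ones.

    Returns
    -------
    list of validated :class:`SubsystemRecord`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _normalize_columns(df, column_map)

    records: list[SubsystemRecord] = []
    seen: set[tuple[str, str]] = set()
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        area = getattr(row, "area")
        if area not in AREAS:
            msg = f"row {i}: unknown area {area!r} for language {row.language!r}"
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg + " (record skipped)")
            n_skipped += 1
            continue
        try:
            erg = int(getattr(row, "ergative"))
        except ValueError:
            raise ValidationError(
                f"row {i}: non-numeric ergative value {row.ergative!r}"
            ) from None
        if erg not in (0, 1):
            raise ValidationError(f"row {i}: ergative must be 0 or 1, got {erg}")
        key = (row.language, row.subsystem)
        if key in seen:
            raise ValidationError(
                f"duplicate (language, subsystem) pair {key!r}"
            )
        seen.add(key)
        records.append(
            SubsystemRecord(
                language_id=row.language,
                family_autotyp=row.autotyp_family,
                family_glottolog=row.glottolog_family,
                area=area,
                subsystem_label=row.subsystem,
                ergative=erg,
            )
        )
    if not records:
        warnings.warn(f"{path}: no valid records read")
    summary = database_summary(records)
    logger.info("read %s: %s", path, summary)
    return records


def write_database(records: Iterable[SubsystemRecord], path: str | Path) -> None:
    """Write records back to the canonical CSV schema (UTF-8, quoted)."""
    rows = [
        {
            "language": r.language_id,
            "autotyp_family": r.family_autotyp,
            "glottolog_family": r.family_glottolog,
            "area": r.area,
            "subsystem": r.subsystem_label,
            "ergative": r.ergative,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8"
    )


def database_summary(records: Sequence[SubsystemRecord]) -> dict:
    """Bookkeeping counts: records, languages, families per taxonomy, singletons.

    Family counts here are *before* area-splitting; singleton counts are
    families with exactly one member language (identical under a taxonomy's
    own grouping).
    """
    langs = {r.language_id for r in records}
    out = {"n_records": len(records), "n_languages": len(langs)}
    for tax in TAXONOMIES:
        fam_langs: dict[str, set[str]] = {}
        for r in records:
            fam_langs.setdefault(r.family(tax), set()).add(r.language_id)
        out[f"n_families_{tax}"] = len(fam_langs)
        out[f"n_singletons_{tax}"] = sum(1 for s in fam_langs.values() if len(s) == 1)
    return out


def write_summary(records: Sequence[SubsystemRecord], path: str | Path) -> None:
    Path(path).write_text(json.dumps(database_summary(records), indent=2))


def group_families(
    records: Sequence[SubsystemRecord],
    taxonomy: str,
    cutoff: int = DEFAULT_LARGE_CUTOFF,
) -> list[FamilyDataset]:
    """Partition records into per-(family, area) datasets.

    Families straddling two areas (e.g. Austronesian across Eurasia and the
    Pacific) are split into per-area sub-families so that bias can be tested
    separately within each area.  The partition is exhaustive and disjoint:
    every record contributes exactly one trial to exactly one dataset.
    """
    if taxonomy not in TAXONOMIES:
        raise ValueError(f"unknown taxonomy {taxonomy!r}")
    groups: dict[tuple[str, str], list[SubsystemRecord]] = {}
    for r in records:
        groups.setdefault((r.family(taxonomy), r.area), []).append(r)

    # annotate split sub-families so ids stay unique across areas
    fam_areas: dict[str, set[str]] = {}
    for fam, area in groups:
        fam_areas.setdefault(fam, set()).add(area)

    out = []
    for (fam, area), recs in sorted(groups.items()):
        fam_id = fam if len(fam_areas[fam]) == 1 else f"{fam}[{area}]"
        by_lang: dict[str, list[int]] = {}
        for r in recs:
            by_lang.setdefault(r.language_id, []).append(r.ergative)
        out.append(
            FamilyDataset(
                family_id=fam_id,
                taxonomy=taxonomy,
                area=area,
                languages=sorted(by_lang),
                trials=[r.ergative for r in recs],
                trials_by_language=by_lang,
                cutoff=cutoff,
            )
        )
    return out


def ergative_proportion(records: Sequence[SubsystemRecord] | Sequence[int]) -> float:
    """Proportion of a language's subsystems that carry an ergative marker.

    Accepts the language's records or its bare trial values.  A fully
    ergative language scores 1.0; Hindi-style marking confined to one of
    four subsystems scores 0.25.
    """
    if len(records) == 0:
        raise ValueError("no records for language")
    vals = [r.ergative if isinstance(r, SubsystemRecord) else int(r) for r in records]
    return sum(vals) / len(vals)


def _tip_state(trials: Sequence[int]) -> object:
    s = set(trials)
    if s == {0, 1}:
        return FamilyTree.POLYMORPHIC
    return trials[0]


def build_family_tree(
    family: FamilyDataset,
    classification: Mapping[str, Sequence[str]] | None = None,
    external_newick: str | Path | None = None,
) -> FamilyTree:
    """Build the family's tree with tip states.

    Without further information the genealogical classifications are
    rank-based, not resolved phylogenies, so the default tree nests languages
    by their subgroup path (``classification`` maps language id to a tuple of
    nested subgroup names) with polytomies where the classification is flat,
    and assigns length 1 to every edge.  If ``external_newick`` is given its
    topology and branch lengths are used instead, pruned to the family's
    languages.

    A tip is polymorphic when the language's subsystem trials contain both
    values.
    """
    if family.n_languages < 2:
        raise ValueError("tree construction requires at least 2 languages")
    tip_states = {
        lang: _tip_state(family.trials_by_language[lang]) for lang in family.languages
    }

    if external_newick is not None:
        tree = dendropy.Tree.get(path=str(external_newick), schema="newick")
        labels = {t.label for t in tree.taxon_namespace}
        wanted = set(family.languages)
        present = wanted & labels
        missing = sorted(wanted - labels)
        if len(present) < 0.5 * len(wanted):
            raise ValueError(
                "external tree covers fewer than half of the family's languages; "
                f"unmatched tips: {', '.join(missing)}"
            )
        if missing:
            warnings.warn(f"external tree missing tips: {', '.join(missing)}")
        tree = tree.extract_tree_with_taxa_labels(present)
        # suppressing unifurcations after pruning keeps path lengths additive
        tree.suppress_unifurcations()
        tip_states = {lang: tip_states[lang] for lang in sorted(present)}
        return FamilyTree(tree=tree, tip_states=tip_states)

    taxa = dendropy.TaxonNamespace(family.languages)
    tree = dendropy.Tree(taxon_namespace=taxa)

    # nest tips under subgroup-path internal nodes; flat classification -> star
    nodes: dict[tuple, dendropy.Node] = {(): tree.seed_node}
    for lang in family.languages:
        path = tuple(classification.get(lang, ())) if classification else ()
        for depth in range(1, len(path) + 1):
            key = path[:depth]
            if key not in nodes:
                node = dendropy.Node()
                node.edge.length = 1.0
                nodes[key[:-1]].add_child(node)
                nodes[key] = node
        leaf = dendropy.Node(taxon=taxa.get_taxon(lang))
        leaf.edge.length = 1.0
        nodes[path].add_child(leaf)
    return FamilyTree(tree=tree, tip_states=tip_states)
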