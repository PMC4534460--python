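"""Synthetic worlds with the statistical structure the analysis assumes.

Two generative blocks:

* a *binomial-trial* world — families whose trait values are independent
  Bernoulli draws at a stated bias strength (the set-based method's model),
  organised into areas, taxonomies and family sizes so that the corpus
  reader, the classifiers and the extrapolation can all be exercised end to
  end with known ground truth; and
* a *CTMC* block — random rooted trees and forward-simulated two-state
  trait histories at stated gain/loss rates, for parameter-recovery and
  calibration testing of the tree-based engine.

Ground-truth labels live in a sidecar table, never in the database itself.
The default benchmark world (:func:`benchmark_config`) mirrors the marginal
shape of the case-marking corpus: 705 subsystem records over 617 languages,
156 families in one taxonomy and 144 in the other, 80 isolates, five areas,
with ergatives confined to the Pacific and South America.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .corpus import (
    WHOLE_LANGUAGE,
    FamilyDataset,
    FamilyTree,
    SubsystemRecord,
    write_database,
)
from .setbias import AGAINST, NONE, TOWARD

#: subsystem labels used when a language carries more than one trial
_SUBSYSTEMS = ("perfective+main", "imperfective+main",
               "perfective+dependent", "imperfective+dependent")


@dataclass
class AreaConfig:
    """Family inventory and bias regime of one geo-linguistic area."""

    name: str
    large_sizes: list[int] = field(default_factory=list)
    small_sizes: list[int] = field(default_factory=list)
    n_large_unbiased: int = 0
    n_small_toward: int = 0
    n_small_unbiased: int = 0
    strength: float = 0.9
    extra_trial_languages: int = 0
    n_glottolog_merges: int = 0


@dataclass
class WorldConfig:
    areas: list[AreaConfig]
    seed: int = 0
    q_gain: float = 0.05
    q_loss: float = 0.30

    def validate(self) -> None:
        for a in self.areas:
            if not 0.5 <= a.strength <= 1.0:
                raise ValueError(f"{a.name}: strength must be in [0.5, 1]")
            if any(s > 4 for s in a.small_sizes):
                raise ValueError(f"{a.name}: small families have 1-4 members")


def _trial_value(direction: str, strength: float, rng: np.random.Generator) -> int:
    """One Bernoulli trial: Pr(trait = direction's value) = strength."""
    if direction == NONE:
        return int(rng.random() < 0.5)
    hit = rng.random() < strength
    if direction == TOWARD:
        return int(hit)
    return int(not hit)


def gen_family(
    size: int,
    direction: str,
    strength: float,
    trials_per_language: int = 1,
    rng: np.random.Generator | None = None,
    family_id: str = "fam",
    area: str = "Eurasia",
    taxonomy: str = "autotyp",
) -> FamilyDataset:
    """Generate one family of independent Bernoulli trials."""
    if not 0.5 <= strength <= 1.0:
        raise ValueError("strength must be in [0.5, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    by_lang: dict[str, list[int]] = {}
    trials: list[int] = []
    for i in range(size):
        lang = f"{family_id}-L{i:03d}"
        vals = [_trial_value(direction, strength, rng)
                for _ in range(trials_per_language)]
        by_lang[lang] = vals
        trials.extend(vals)
    return FamilyDataset(
        family_id=family_id, taxonomy=taxonomy, area=area,
        languages=sorted(by_lang), trials=trials, trials_by_language=by_lang,
    )


def gen_tree(n_tips: int, rng: np.random.Generator,
             tip_prefix: str = "t") -> FamilyTree:
    """Random rooted binary topology by sequential random joins, unit edges."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    labels = [f"{tip_prefix}{i}" for i in range(n_tips)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    subtrees = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.edge.length = 1.0
        subtrees.append(node)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.add_child(left)
        parent.add_child(right)
        subtrees.append(parent)
    root = subtrees[0]
    root.edge.length = None
    tree.seed_node = root
    return FamilyTree(tree=tree, tip_states={lab: 0 for lab in labels})


def simulate_ctmc(
    family_tree: FamilyTree,
    q_gain: float,
    q_loss: float,
    root_state: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, int], list[tuple[str, float, int, int]]]:
    """Forward-simulate the two-state chain down every branch.

    Exponential waiting times between state flips; returns the tip states
    and an event log of (node label, time along branch, from, to).  With
    ``root_state=None`` the root is drawn from the stationary distribution
    (uniform when both rates are 0).
    """
    if q_gain < 0 or q_loss < 0:
        raise ValueError("rates must be nonnegative")
    rng = rng if rng is not None else np.random.default_rng()
    q = q_gain + q_loss
    if root_state is None:
        p1 = q_gain / q if q > 0 else 0.5
        root_state = int(rng.random() < p1)
    states = {id(family_tree.tree.seed_node): root_state}
    events: list[tuple[str, float, int, int]] = []
    tips: dict[str, int] = {}
    for node in family_tree.tree.preorder_node_iter():
        if node is family_tree.tree.seed_node:
            s = root_state
        else:
            s = states[id(node.parent_node)]
            t_total = float(node.edge.length or 0.0)
            t = 0.0
            while True:
                rate = q_gain if s == 0 else q_loss
                if rate <= 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= t_total:
                    break
                label = node.taxon.label if node.taxon else f"node{id(node) % 9973}"
                events.append((label, t, s, 1 - s))
                s = 1 - s
            states[id(node)] = s
        if node.is_leaf():
            tips[node.taxon.label] = s
    return tips, events


def _area_code(name: str) -> str:
    return "".join(w[0] for w in name.split()).upper()


def gen_world(config: WorldConfig) -> tuple[list[SubsystemRecord], pd.DataFrame]:
    """Generate a full synthetic database plus its ground-truth sidecar.

    The family inventory (sizes, directions, strengths, glottolog merges,
    which languages carry an extra subsystem trial) is deterministic from
    the config; only the trial values are random, drawn from the per-family
    bias regime under the master seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SubsystemRecord] = []
    truth_rows = []
    for area in config.areas:
        code = _area_code(area.name)
        fams: list[tuple[str, int, str, float, bool]] = []
        for i, size in enumerate(area.large_sizes):
            direction = NONE if i < area.n_large_unbiased else AGAINST
            fams.append((f"{code}-LG{i:02d}", size, direction, area.strength, True))
        for i, size in enumerate(area.small_sizes):
            if i < area.n_small_unbiased:
                direction = NONE
            elif i < area.n_small_unbiased + area.n_small_toward:
                direction = TOWARD
            else:
                direction = AGAINST
            fams.append((f"{code}-SM{i:02d}", size, direction, area.strength, False))

        # merge pairs of adjacent multi-language small families in glottolog
        glottolog_of = {fid: fid for fid, *_ in fams}
        multi_small = [fid for fid, size, _, _, lg in fams if not lg and size >= 2]
        for m in range(area.n_glottolog_merges):
            a_id, b_id = multi_small[2 * m], multi_small[2 * m + 1]
            glottolog_of[a_id] = glottolog_of[b_id] = f"{code}-GM{m:02d}"

        extra_left = area.extra_trial_languages
        for fid, size, direction, strength, is_large in fams:
            s = strength if direction != NONE else 0.5
            truth_rows.append({
                "family": fid, "glottolog_family": glottolog_of[fid],
                "area": area.name, "size": size, "direction": direction,
                "strength": strength if direction != NONE else 0.5,
                "is_large": is_large,
            })
            for j in range(size):
                lang = f"{fid}-L{j:03d}"
                n_trials = 1
                if is_large and extra_left > 0:
                    n_trials = 2
                    extra_left -= 1
                labels = ([WHOLE_LANGUAGE] if n_trials == 1
                          else list(_SUBSYSTEMS[:n_trials]))
                for lab in labels:
                    records.append(SubsystemRecord(
                        language_id=lang, family_autotyp=fid,
                        family_glottolog=glottolog_of[fid], area=area.name,
                        subsystem_label=lab,
                        ergative=_trial_value(direction, s, rng),
                    ))
        if extra_left > 0:
            raise ValueError(
                f"{area.name}: not enough large-family languages for "
                f"{area.extra_trial_languages} extra trials")
    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_world(config: WorldConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the synthetic database (CSV) and truth sidecar (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = gen_world(config)
    db = out / "database.csv"
    tr = out / "truth.tsv"
    write_database(records, db)
    truth.to_csv(tr, sep="\t", index=False)
    return db, tr


def benchmark_config(seed: int = 0) -> WorldConfig:
    """The benchmark world: corpus-shaped marginals with known truth.

    705 records / 617 languages / 156 + 144 families / 80 isolates; the
    trait is absent everywhere in Africa (a strength-1 bias against it),
    biased against at strength 0.9 in the other areas' biased families, and
    present mainly in Pacific and South America small families.
    """
    areas = [
        AreaConfig("Africa",
                   large_sizes=[5, 6, 7, 9, 11, 14, 18, 25],
                   small_sizes=[2, 3, 4, 2, 3, 4, 2, 3] + [1] * 16,
                   n_large_unbiased=0, strength=1.0,
                   extra_trial_languages=18, n_glottolog_merges=3),
        AreaConfig("Eurasia",
                   large_sizes=[5, 6, 8, 10, 13, 17, 22],
                   small_sizes=[2, 3, 4, 2, 3, 4, 2, 3] + [1] * 16,
                   n_large_unbiased=1, n_small_toward=2, strength=0.9,
                   extra_trial_languages=18, n_glottolog_merges=2),
        AreaConfig("Pacific",
                   large_sizes=[5, 6, 7, 8, 10, 12, 15, 18],
                   small_sizes=[2, 3, 4, 2, 3, 4, 2, 3] + [1] * 16,
                   n_large_unbiased=3, n_small_toward=6, n_small_unbiased=2,
                   strength=0.9,
                   extra_trial_languages=18, n_glottolog_merges=3),
        AreaConfig("South America",
                   large_sizes=[5, 6, 8, 10, 12],
                   small_sizes=[2, 3, 4, 2, 3, 4, 2, 3] + [1] * 16,
                   n_large_unbiased=1, n_small_toward=4, n_small_unbiased=2,
                   strength=0.9,
                   extra_trial_languages=16, n_glottolog_merges=2),
        AreaConfig("Rest of the Americas",
                   large_sizes=[5, 6, 8, 10, 12, 15, 28, 40],
                   small_sizes=[2, 3, 4, 2, 3, 4, 2, 3] + [1] * 16,
                   n_large_unbiased=1, n_small_toward=1, strength=0.9,
                   extra_trial_languages=18, n_glottolog_merges=2),
    ]
    return WorldConfig(areas=areas, seed=seed)
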