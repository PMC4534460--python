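import itertools
import math

import numpy as np
import pytest

import famdrift as fd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_world():
    """The corpus-shaped benchmark world (records + truth), generated once."""
    return fd.gen_world(fd.benchmark_config(seed=1))


@pytest.fixture(scope="session")
def benchmark_db(tmp_path_factory):
    out = tmp_path_factory.mktemp("world")
    db, truth = fd.write_world(fd.benchmark_config(seed=1), out)
    return db, truth


def make_family(trials_by_language, family_id="fam", area="Eurasia",
                taxonomy="autotyp", cutoff=5):
    """Build a FamilyDataset directly from {language: [trial values]}."""
    trials = [v for vals in trials_by_language.values() for v in vals]
    return fd.FamilyDataset(
        family_id=family_id, taxonomy=taxonomy, area=area,
        languages=sorted(trials_by_language), trials=trials,
        trials_by_language=dict(trials_by_language), cutoff=cutoff,
    )


def enum_loglik(family_tree, q_gain, q_loss, root_prior="stationary"):
    """Brute-force CTMC likelihood: sum over all internal-node state
    assignments.  Independent of the pruning implementation; feasible for
    trees with a handful of tips only."""
    tree = family_tree.tree
    nodes = list(tree.postorder_node_iter())
    q = q_gain + q_loss
    if root_prior == "stationary" and q > 0:
        pi = [q_loss / q, q_gain / q]
    else:
        pi = [0.5, 0.5]

    def P(i, j, t):
        if q <= 0 or t <= 0:
            return 1.0 if i == j else 0.0
        pi1, pi0 = q_gain / q, q_loss / q
        e = math.exp(-q * t)
        M = [[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]]
        return M[i][j]

    internals = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        p = pi[amap[id(tree.seed_node)]]
        for n in nodes:
            if n is tree.seed_node:
                continue
            ps = amap[id(n.parent_node)]
            t = n.edge.length
            if n.is_leaf():
                s = family_tree.tip_states[n.taxon.label]
                if s == "polymorphic":
                    p *= P(ps, 0, t) + P(ps, 1, t)
                else:
                    p *= P(ps, int(s), t)
            else:
                p *= P(ps, amap[id(n)], t)
        total += p
    return math.log(total)


def random_stated_tree(rng, n_min=2, n_max=5, allow_poly=True):
    """A random small tree with random (possibly polymorphic) tip states,
    guaranteed non-degenerate (likelihood > 0 for positive rates)."""
    n = int(rng.integers(n_min, n_max + 1))
    ft = fd.gen_tree(n, rng)
    choices = [0, 1, "polymorphic"] if allow_poly else [0, 1]
    ft.tip_states = {lab: choices[rng.integers(len(choices))]
                     for lab in ft.tip_labels()}
    return ft


def g2_oracle(table):
    """Closed-form G-squared statistics for the area x direction table.

    Independence-model fitted values are products of the margins; the
    area-only model splits each row half and half.  Returns (interaction,
    bias-term) statistics.
    """
    O = np.asarray(table, dtype=float)
    N = O.sum()
    row, col = O.sum(1), O.sum(0)

    def g2(O, E):
        mask = O > 0
        return 2.0 * (O[mask] * np.log(O[mask] / E[mask])).sum()

    return g2(O, np.outer(row, col) / N), g2(O, np.outer(row, [0.5, 0.5]))
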