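"""Ground-truthed synthetic benchmarks and cluster-evaluation metrics.

Two generators emulate the data a microbial-association-network pipeline
would see.  The first integrates generalized Lotka-Volterra (gLV) dynamics
``dx/dt = x ∘ (b + A·x)`` with per-condition growth rates shaped by
environmental factors, so species sort into environmentally induced
clusters on top of a sparse random interaction network.  The second plants
additive biclusters (signal blocks over feature × sample rectangles) in a
noise matrix, emulating ecosystems without biotic interactions whose
correlation networks are dense.  Both feed :func:`infer_network`, which
builds a significance-filtered correlation network, the algorithm's actual
input.

Noise injectors (entry permutation, multinomial resampling of scaled
counts, affine weight shifting) reproduce common degradations of real
abundance data.  :func:`evaluate` scores a predicted assignment against
the ground truth with the contingency-matrix metrics Sn, PPV,
Acc = sqrt(Sn·PPV) and separation, plus pathological-assignment filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .clustering import ClusterAssignment
from .graph_io import SignedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticDataset",
    "EvaluationResult",
    "generate_glv",
    "generate_biclusters",
    "infer_network",
    "permute_fraction",
    "add_multinomial_noise",
    "shift_weights",
    "evaluate",
]


@dataclass
class SyntheticDataset:
    """Abundance matrix (species × samples) with ground-truth labels."""

    abundances: pd.DataFrame
    truth: Dict[str, int]
    condition_labels: Dict[str, int]
    interaction_matrix: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)


@dataclass
class EvaluationResult:
    """Contingency-matrix scores of a predicted clustering.

    ``pathological`` marks assignments the benchmark filters out: one
    cluster holding more than 80% of the nodes, or more than 50 clusters.
    """

    Sn: float
    PPV: float
    Acc: float
    Sep: float
    sparsity: Optional[float] = None
    pathological: bool = False
    reason: Optional[str] = None


# -- gLV generator ---------------------------------------------------------

#: Abundances above this multiple of the initial community total abort the
#: integration and trigger regeneration of the interaction matrix.
EXPLOSION_FACTOR = 1e6

_RETRY_BUDGET = 100


def _random_interactions(rng, n_species: int, connectivity: float,
                         strength: float = 0.5) -> np.ndarray:
    """Sparse random interaction matrix: off-diagonal entries nonzero with
    probability ``connectivity``, drawn uniform in ±``strength``; diagonal
    −1 (self-limitation)."""
    a = np.zeros((n_species, n_species))
    mask = rng.random((n_species, n_species)) < connectivity
    np.fill_diagonal(mask, False)
    a[mask] = rng.uniform(-strength, strength, size=int(mask.sum()))
    np.fill_diagonal(a, -1.0)
    return a


def _condition_growth_rates(rng, n_species: int, n_conditions: int,
                            n_factors: int = 3) -> np.ndarray:
    """Per-condition growth rates shaped by environmental factors.

    Each species' susceptibility to each factor is N(1, 1); each
    condition's factor strengths are |N(3, 1)| with one factor kept
    positive and the others flipped negative.  Rotating which factor is
    positive makes each condition's cumulative effect unique.  Returns an
    ``n_species × n_conditions`` matrix.
    """
    effects = rng.normal(1.0, 1.0, size=(n_species, n_factors))
    base = rng.uniform(0.5, 1.0, size=n_species)
    rates = np.empty((n_species, n_conditions))
    for c in range(n_conditions):
        strengths = np.abs(rng.normal(3.0, 1.0, size=n_factors))
        signs = -np.ones(n_factors)
        signs[c % n_factors] = 1.0
        rates[:, c] = base + effects @ (signs * strengths)
    return rates


def _integrate_glv(a: np.ndarray, b: np.ndarray, x0: np.ndarray, rng,
                   noise_sd: float = 0.5, dt: float = 0.01,
                   steps: int = 2500) -> Optional[np.ndarray]:
    """Explicit fixed-step integration of stochastic gLV dynamics.

    The drift is ``x ∘ (b + A·x)``; each step additionally applies
    multiplicative log-normal environmental noise with standard deviation
    ``noise_sd·sqrt(dt)``, so abundances fluctuate around their
    deterministic attractor instead of freezing onto it.  ``x0`` is
    species × samples; all samples of a condition integrate as one matrix.
    Abundances are clipped at zero (extinction).  Returns ``None`` on
    population explosion.
    """
    x = x0.copy()
    limit = EXPLOSION_FACTOR * x0.sum()
    scale = noise_sd * math.sqrt(dt)
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(steps):
            x = x + dt * x * (b[:, None] + a @ x)
            if scale > 0:
                x = x * np.exp(rng.normal(0.0, scale, size=x.shape))
            np.clip(x, 0.0, None, out=x)
            if step % 50 == 0 and (not np.all(np.isfinite(x)) or x.max() > limit):
                return None
    if not np.all(np.isfinite(x)) or x.max() > limit:
        return None
    return x


def generate_glv(
    n_species: int = 100,
    n_conditions: int = 2,
    connectivity: float = 0.05,
    samples_per_condition: int = 50,
    seed: int = 0,
    n_factors: int = 3,
    noise_sd: float = 0.5,
) -> SyntheticDataset:
    """Simulate species abundances under stochastic gLV dynamics with
    environmental clusters.

    A sparse random interaction matrix (nonzero off-diagonal probability =
    ``connectivity``) is combined with per-condition growth rates; each
    sample is an independent stochastic integration from random initial
    abundances, sampled once the dynamics are quasi-stationary, so
    within-condition variation comes from environmental noise and
    differential extinction rather than collapsing onto a shared fixed
    point.  Interaction matrices causing population explosions are
    regenerated (budget 100).  Ground-truth labels come from K-means
    (k = ``n_conditions``, 10 restarts) on the species abundance profiles.
    """
    if not (0 < connectivity < 1):
        raise ValueError("connectivity must be in (0, 1)")
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(seed)
    for attempt in range(_RETRY_BUDGET):
        a = _random_interactions(rng, n_species, connectivity)
        rates = _condition_growth_rates(rng, n_species, n_conditions, n_factors)
        blocks = []
        for c in range(n_conditions):
            x0 = rng.uniform(0.1, 1.1, size=(n_species, samples_per_condition))
            final = _integrate_glv(a, rates[:, c], x0, rng, noise_sd)
            if final is None:
                break
            blocks.append(final)
        if len(blocks) == n_conditions:
            break
        logger.info("population explosion; regenerating (attempt %d)", attempt + 1)
    else:
        raise RuntimeError(
            f"no stable interaction matrix found in {_RETRY_BUDGET} attempts "
            f"(n_species={n_species}, connectivity={connectivity})"
        )

    species = [f"sp{i}" for i in range(n_species)]
    columns, condition_labels = [], {}
    for c in range(n_conditions):
        for s in range(samples_per_condition):
            name = f"c{c}_s{s}"
            columns.append(name)
            condition_labels[name] = c
    abundances = pd.DataFrame(np.hstack(blocks), index=species, columns=columns)

    km = KMeans(n_clusters=n_conditions, n_init=10,
                random_state=int(rng.integers(0, 2**31 - 1)))
    labels = km.fit_predict(abundances.values)
    truth = {sp: int(lbl) for sp, lbl in zip(species, labels)}
    return SyntheticDataset(
        abundances=abundances,
        truth=truth,
        condition_labels=condition_labels,
        interaction_matrix=a,
        params={
            "generator": "glv",
            "n_species": n_species,
            "n_conditions": n_conditions,
            "connectivity": connectivity,
            "samples_per_condition": samples_per_condition,
            "n_factors": n_factors,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# -- bicluster generator ---------------------------------------------------


def generate_biclusters(
    n_features: int = 100,
    n_samples: int = 100,
    n_clusters: int = 2,
    positions: Optional[Sequence[Tuple[Sequence[int], Sequence[int]]]] = None,
    signal: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Plant rank-one signal blocks at set positions in a noise matrix.

    Each block is an outer product of positive feature loadings
    (signal·|N(1, 1/3)|, so ``signal`` scales the block amplitude) and
    per-sample activations (N(2, 1) on the block's samples, 0 elsewhere);
    blocks active in disjoint sample ranges
    anti-correlate, producing negative edges between block groups in the
    inferred network.  The matrix is shifted by its minimum so abundances
    are nonnegative; the affine shift leaves every correlation — and hence
    the inferred network — unchanged.  Ground truth assigns block features their block id
    (1..B); any feature outside every block is background (label 0).
    Feature blocks must be disjoint.
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        # blocks tile the whole feature set, as in bicluster evaluations
        # where every feature belongs to a true-positive cluster; the
        # resulting networks are dense (two near-cliques joined by negative
        # edges), the opposite topology regime from the gLV generator
        block_feats = n_features // n_clusters
        span = n_samples // n_clusters
        positions = [
            (range(b * block_feats,
                   (b + 1) * block_feats if b < n_clusters - 1 else n_features),
             range(b * span,
                   (b + 1) * span if b < n_clusters - 1 else n_samples))
            for b in range(n_clusters)
        ]
    seen: set = set()
    for feats, _ in positions:
        feats = set(feats)
        if feats & seen:
            raise ValueError("planted feature blocks must be disjoint")
        seen |= feats

    matrix = rng.normal(0.0, noise_sd, size=(n_features, n_samples))
    truth = {f"f{i}": 0 for i in range(n_features)}
    for b, (feats, samples) in enumerate(positions, start=1):
        feats = np.fromiter(feats, dtype=int)
        samples = np.fromiter(samples, dtype=int)
        loadings = signal * np.abs(rng.normal(1.0, 1.0 / 3.0, size=feats.size))
        activations = rng.normal(2.0, 1.0, size=samples.size)
        matrix[np.ix_(feats, samples)] += np.outer(loadings, activations)
        for i in feats:
            truth[f"f{i}"] = b

    abundances = pd.DataFrame(
        matrix - matrix.min(),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    condition_labels = {f"s{j}": 0 for j in range(n_samples)}
    for b, (_, samples) in enumerate(positions, start=1):
        for j in samples:
            condition_labels[f"s{j}"] = b
    return SyntheticDataset(
        abundances=abundances,
        truth=truth,
        condition_labels=condition_labels,
        interaction_matrix=None,
        params={
            "generator": "biclusters",
            "n_features": n_features,
            "n_samples": n_samples,
            "n_clusters": n_clusters,
            "signal": signal,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# -- network inference -----------------------------------------------------


def infer_network(
    abundances: Union[pd.DataFrame, np.ndarray],
    method: str = "pearson",
    alpha: float = 0.05,
) -> SignedGraph:
    """Significance-filtered correlation network from an abundance matrix.

    Rows are taxa, columns samples.  Pairwise Pearson (or Spearman)
    correlations are kept as signed edge weights when the two-sided
    p-value from the t-approximation is below ``alpha``.  Constant rows
    have undefined correlations and are excluded with a warning.
    """
    if not isinstance(abundances, pd.DataFrame):
        abundances = pd.DataFrame(np.asarray(abundances, dtype=float))
        abundances.index = [f"f{i}" for i in range(abundances.shape[0])]
    values = abundances.values.astype(float)
    n_samples = values.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples to test correlations")

    keep = values.std(axis=1) > 0
    if not keep.all():
        logger.warning(
            "excluding %d constant row(s) with undefined correlation",
            int((~keep).sum()),
        )
    values = values[keep]
    names = [str(n) for n in abundances.index[keep]]
    if len(names) < 2:
        return SignedGraph([], nodes=names)
    if method == "spearman":
        values = np.apply_along_axis(stats.rankdata, 1, values)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")

    r = np.corrcoef(values)
    df = n_samples - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r_clipped = np.clip(r, -1.0, 1.0)
        t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isnan(p)] = 0.0  # |r| = 1 exactly

    edges = []
    n = len(names)
    iu, ju = np.triu_indices(n, k=1)
    sig = (p[iu, ju] < alpha) & (r_clipped[iu, ju] != 0.0)
    for i, j in zip(iu[sig], ju[sig]):
        edges.append((names[i], names[j], float(r_clipped[i, j])))
    return SignedGraph(edges, nodes=names)


# -- noise injectors -------------------------------------------------------


def permute_fraction(
    abundances: Union[pd.DataFrame, np.ndarray],
    fraction: float,
    seed: int = 0,
    mode: str = "global",
) -> Union[pd.DataFrame, np.ndarray]:
    """Shuffle a fraction of matrix entries uniformly.

    ``ceil(fraction × cells)`` positions are selected without replacement
    and their values permuted among themselves.  ``mode`` controls the
    shuffling scope: ``global`` (default) permutes across the whole matrix,
    ``rows``/``columns`` select and permute within each row/column.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    frame = isinstance(abundances, pd.DataFrame)
    values = (abundances.values if frame else np.asarray(abundances)).copy()
    rng = np.random.default_rng(seed)
    if fraction > 0:
        if mode == "global":
            flat = values.reshape(-1)
            m = math.ceil(fraction * flat.size)
            pos = rng.choice(flat.size, size=m, replace=False)
            flat[pos] = flat[pos][rng.permutation(m)]
        elif mode in ("rows", "columns"):
            mat = values if mode == "rows" else values.T
            for row in mat:
                m = math.ceil(fraction * row.size)
                pos = rng.choice(row.size, size=m, replace=False)
                row[pos] = row[pos][rng.permutation(m)]
        else:
            raise ValueError("mode must be 'global', 'rows' or 'columns'")
    if frame:
        return pd.DataFrame(values, index=abundances.index, columns=abundances.columns)
    return values


def add_multinomial_noise(
    abundances: Union[pd.DataFrame, np.ndarray],
    scale: float = 1000.0,
    seed: int = 0,
) -> Union[pd.DataFrame, np.ndarray]:
    """Resample each sample's counts from a multinomial.

    Per sample (column), the total is the original column sum scaled by
    ``scale`` (rounded) and the event probabilities are proportional to the
    abundances — emulating sequencing-depth noise on scaled counts.
    Zero-abundance species stay zero; all-zero samples stay zero.
    """
    frame = isinstance(abundances, pd.DataFrame)
    values = (abundances.values if frame else np.asarray(abundances)).astype(float)
    if (values < 0).any():
        raise ValueError("abundances must be nonnegative")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(values)
    for j in range(values.shape[1]):
        total = values[:, j].sum()
        if total == 0:
            continue
        n = int(round(total * scale))
        out[:, j] = rng.multinomial(n, values[:, j] / total)
    if frame:
        return pd.DataFrame(out, index=abundances.index, columns=abundances.columns)
    return out


def shift_weights(g: SignedGraph) -> SignedGraph:
    """Affinely map edge weights from [−1, 1] to [0, 1]: w' = (w + 1) / 2.

    Emulates pipelines that rescale correlations to remove negative
    weights.  A weight of exactly −1 maps to 0 and the edge is dropped
    with a warning (zero weights are excluded by the graph invariant).
    """
    edges = []
    dropped = 0
    for u, v, w in g.edges():
        shifted = (w + 1.0) / 2.0
        if shifted == 0.0:
            dropped += 1
            continue
        edges.append((u, v, shifted))
    if dropped:
        logger.warning("%d edge(s) with weight −1 mapped to 0 and dropped", dropped)
    return SignedGraph(edges, nodes=g.nodes)


# -- evaluation ------------------------------------------------------------


def _contingency(truth: Mapping[str, int], predicted: Mapping[str, int]):
    t_ids = sorted(set(truth.values()))
    p_ids = sorted(set(predicted.values()))
    t_index = {c: i for i, c in enumerate(t_ids)}
    p_index = {c: j for j, c in enumerate(p_ids)}
    table = np.zeros((len(t_ids), len(p_ids)))
    for node, p_cid in predicted.items():
        table[t_index[truth[node]], p_index[p_cid]] += 1
    return table, t_ids, p_ids


def evaluate(
    predicted: Union[ClusterAssignment, Mapping[str, int]],
    truth: Mapping[str, int],
) -> EvaluationResult:
    """Score a predicted clustering against ground-truth labels.

    Weakly flagged nodes count as unassigned and are excluded from the
    contingency table T (t_ij = |truth cluster i ∩ predicted cluster j|).
    With n_i the full truth-cluster sizes and the column sums m_j:

    - Sn  = Σ_i max_j t_ij / Σ_i n_i          (complex-wise sensitivity)
    - PPV = Σ_j max_i t_ij / Σ_j m_j          (cluster-wise PPV)
    - Acc = sqrt(Sn · PPV)
    - Sep = sqrt(Sep_co · Sep_cl) where sep_ij = t_ij² / (row_i · col_j),
      Sep_co averages row sums of sep and Sep_cl averages column sums —
      the product of the fraction of assigned nodes in the true cluster
      and of true nodes in the assigned cluster, penalizing overlap.

    The pathological filters fire when one predicted cluster exceeds 80%
    of the nodes or more than 50 clusters are predicted.
    """
    if isinstance(predicted, ClusterAssignment):
        membership = {
            n: c for n, c in predicted.membership.items()
            if not predicted.weak.get(n, False)
        }
        full_membership = predicted.membership
    else:
        membership = dict(predicted)
        full_membership = membership
    if not full_membership:
        raise ValueError("empty prediction")
    unknown = set(full_membership) - set(truth)
    if unknown:
        raise ValueError(f"predicted nodes missing from truth: {sorted(unknown)[:5]}")

    n_total = len(full_membership)
    sizes: Dict[int, int] = {}
    for cid in full_membership.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    pathological, reason = False, None
    if max(sizes.values()) > 0.8 * n_total:
        pathological, reason = True, "one cluster holds more than 80% of nodes"
    elif len(sizes) > 50:
        pathological, reason = True, "more than 50 clusters"

    if not membership:
        raise ValueError("every node is weakly assigned; nothing to evaluate")
    table, _, _ = _contingency(truth, membership)
    truth_sizes = np.array(
        [sum(1 for v in truth.values() if v == c) for c in sorted(set(truth.values()))],
        dtype=float,
    )
    col_sums = table.sum(axis=0)
    row_sums = table.sum(axis=1)

    sn = table.max(axis=1).sum() / truth_sizes.sum()
    ppv = table.max(axis=0).sum() / col_sums.sum()
    acc = math.sqrt(sn * ppv)

    with np.errstate(divide="ignore", invalid="ignore"):
        sep_ij = np.where(
            (row_sums[:, None] > 0) & (col_sums[None, :] > 0),
            table**2 / (row_sums[:, None] * col_sums[None, :]),
            0.0,
        )
    sep_co = sep_ij.sum(axis=1).mean()
    sep_cl = sep_ij.sum(axis=0).mean()
    sep = math.sqrt(sep_co * sep_cl)

    return EvaluationResult(
        Sn=float(sn), PPV=float(ppv), Acc=float(acc), Sep=float(sep),
        pathological=pathological, reason=reason,
    )
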