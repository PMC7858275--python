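"""OTU-table processing and community statistics.

Covers the normalization and hypothesis-testing stages applied to larval gut
16S count tables: without-replacement subsampling (rarefaction), sparsity
filtering, Shannon/Pielou alpha diversity, Bray-Curtis dissimilarity,
non-metric multidimensional scaling (Kruskal stress-1, isotonic disparities,
majorization updates), one-way PERMANOVA with a label-permutation null, and
the Mantel matrix-correlation test.

The permutation tests support two modes: Monte-Carlo permutations with the
standard ``(hits + 1) / (n_perm + 1)`` estimator, and exhaustive enumeration
of all distinct label assignments for small designs, where the p-value is the
exact fraction of assignments (including the observed one) reaching the
observed statistic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

log = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "rarefy",
    "rarefaction_curve",
    "prevalence_filter",
    "shannon_evenness",
    "alpha_diversity_table",
    "bray_curtis",
    "nmds",
    "permanova",
    "mantel",
    "alpha_group_tests",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Samples x taxa integer counts with taxonomy lineages and sample metadata.

    ``counts`` rows are samples, columns taxa.  ``taxonomy`` maps taxon id to
    a semicolon-separated rank lineage; ``metadata`` is indexed by sample id
    with at least ``diet``, ``day`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.columns.duplicated().any() or self.counts.index.duplicated().any():
            raise ValueError("duplicate sample or taxon ids")
        if self.metadata is not None:
            missing = self.counts.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing samples: {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Row-normalized relative abundances."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def subset(self, samples: list[str]) -> "AbundanceTable":
        meta = self.metadata.loc[samples] if self.metadata is not None else None
        return AbundanceTable(self.counts.loc[samples].copy(), self.taxonomy, meta)


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise dissimilarities with sample ids."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    n_iterations: int
    converged: bool
    best_start: int
    all_stresses: list[float] = field(default_factory=list)
    stress_trace: list[float] = field(default_factory=list)  # best start, per iteration


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    r2: float | None = None
    pairwise: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int, seed: int | np.random.Generator = 0) -> AbundanceTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning, per
    the usual convention when normalizing to the smallest retained size.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = table.depths[table.depths >= depth].index
    dropped = table.counts.index.difference(keep)
    if len(dropped):
        log.warning("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, list(dropped))
    rows = {}
    for sid in keep:
        counts = table.counts.loc[sid].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows[sid] = counts
        else:
            rows[sid] = rng.multivariate_hypergeometric(counts, depth, method="marginals")
    sub = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    sub.columns = table.counts.columns
    meta = table.metadata.loc[list(keep)] if table.metadata is not None else None
    return AbundanceTable(sub, table.taxonomy, meta)


def rarefaction_curve(table: AbundanceTable, depths: list[int], n_reps: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth."""
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        richness = {sid: [] for sid in table.sample_ids}
        for _ in range(n_reps):
            sub = rarefy(table, depth, rng)
            for sid in sub.sample_ids:
                richness[sid].append(int((sub.counts.loc[sid] > 0).sum()))
        for sid, vals in richness.items():
            if vals:
                rows.append({"sample": sid, "depth": depth,
                             "mean_richness": float(np.mean(vals))})
    return pd.DataFrame(rows)


def prevalence_filter(table: AbundanceTable, min_count: int = 4,
                      min_sample_frac: float = 0.10,
                      mode: str = "count_threshold") -> AbundanceTable:
    """Remove overly sparse taxa.

    ``count_threshold`` (default): keep taxa whose count is >= ``min_count``
    in at least ``ceil(min_sample_frac * n_samples)`` samples.  The
    alternative reading, presence in at least ``min_count`` samples, is
    available as ``mode='sample_presence'``.
    """
    if min_count <= 0 or min_sample_frac <= 0:
        raise ValueError("thresholds must be positive")
    n = len(table.counts)
    if mode == "count_threshold":
        need = math.ceil(min_sample_frac * n)
        keep = (table.counts >= min_count).sum(axis=0) >= need
    elif mode == "sample_presence":
        keep = (table.counts > 0).sum(axis=0) >= min_count
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = table.counts.loc[:, keep]
    tax = table.taxonomy[kept.columns] if table.taxonomy is not None else None
    return AbundanceTable(kept.copy(), tax, table.metadata)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon_evenness(counts: "np.ndarray | list[float]") -> tuple[float, float, int]:
    """Shannon index H' (natural log), Pielou evenness J = H'/ln(S), richness S.

    J is defined as 0 for a single-taxon sample (H' is 0 there and the
    ln(S) normalizer vanishes).
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero count vector")
    p = x / x.sum()
    h = float(-(p * np.log(p)).sum())
    s = int(x.size)
    j = h / math.log(s) if s > 1 else 0.0
    return h, j, s


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample H', J and observed richness, joined with metadata."""
    rows = {}
    for sid in table.sample_ids:
        h, j, s = shannon_evenness(table.counts.loc[sid].to_numpy())
        rows[sid] = {"shannon": h, "pielou": j, "richness": s}
    out = pd.DataFrame.from_dict(rows, orient="index")
    if table.metadata is not None:
        out = out.join(table.metadata)
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: "AbundanceTable | pd.DataFrame", input: str = "counts") -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x - y| / sum(x + y).

    ``input='relative'`` converts rows to proportions first; on counts the
    statistic is computed on the raw integers.
    """
    frame = table.counts if isinstance(table, AbundanceTable) else table
    x = frame.to_numpy(dtype=float)
    sums = x.sum(axis=1)
    if (sums == 0).any():
        bad = list(frame.index[sums == 0])
        raise ValueError(f"all-zero samples: {bad}")
    if input == "relative":
        x = x / sums[:, None]
    elif input != "counts":
        raise ValueError(f"unknown input {input!r}")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = x.sum(axis=1)[:, None] + x.sum(axis=1)[None, :]
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, list(frame.index))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling used as the deterministic first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def _stress1(dhat: np.ndarray, dconf: np.ndarray) -> float:
    denom = (dconf ** 2).sum()
    if denom == 0:
        return math.inf
    return math.sqrt(((dhat - dconf) ** 2).sum() / denom)


def nmds(dist: DistanceMatrix, k: int = 2, n_starts: int = 20, max_iter: int = 1000,
         tol: float = 1e-6, seed: int = 0) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Disparities come from isotonic (pool-adjacent-violators) regression of
    configuration distances on the rank order of the input dissimilarities;
    configurations are updated by the Guttman majorization transform.  The
    first start is classical metric scaling, the rest are random; the lowest
    final stress wins and coordinates are centered.
    """
    n = dist.n
    if n < k + 2:
        raise ValueError("need at least k + 2 samples")
    rng = np.random.default_rng(seed)
    dvec = dist.condensed()
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    ranks = np.arange(dvec.size, dtype=float)

    best: tuple[float, np.ndarray, int, bool, list[float]] | None = None
    all_stresses = []
    for start in range(n_starts):
        if start == 0:
            x = _classical_mds(dist.values, k)
            if np.allclose(x, 0):
                x = rng.normal(size=(n, k))
        else:
            x = rng.normal(size=(n, k))
        prev_stress = math.inf
        converged = False
        stress = math.inf
        n_iter = 0
        trace: list[float] = []
        for n_iter in range(1, max_iter + 1):
            dconf = pdist(x)
            dconf_sorted = dconf[order]
            dhat_sorted = iso.fit_transform(ranks, dconf_sorted)
            dhat = np.empty_like(dhat_sorted)
            dhat[order] = dhat_sorted
            stress = _stress1(dhat, dconf)
            trace.append(stress)
            if prev_stress - stress < tol * max(prev_stress, 1e-12):
                converged = True
                break
            prev_stress = stress
            # Guttman transform with disparities dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dconf > 0, dhat / dconf, 0.0)
            bmat = -squareform(ratio)
            np.fill_diagonal(bmat, -bmat.sum(axis=1))
            x = bmat @ x / n
        all_stresses.append(stress)
        if best is None or stress < best[0]:
            best = (stress, x - x.mean(axis=0), n_iter, converged, trace)

    assert best is not None
    stress, coords, n_iter, converged, trace = best
    if not converged:
        log.warning("nmds: best start did not converge (stress=%.4f)", stress)
    return OrdinationResult(coordinates=coords, stress=stress, n_iterations=n_iter,
                            converged=converged,
                            best_start=int(np.argmin(all_stresses)),
                            all_stresses=all_stresses, stress_trace=trace)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """PERMANOVA pseudo-F and R^2 from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within == 0 or df_within == 0:
        return math.inf if ss_between > 0 else 0.0, ss_between / ss_total if ss_total else 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _enumerate_assignments(codes: np.ndarray, cap: int = 200_000):
    """Distinct multiset permutations of the label vector, lazily, capped."""
    counts = np.bincount(codes)
    total = math.factorial(codes.size)
    for c in counts:
        total //= math.factorial(int(c))
    if total > cap:
        raise ValueError(f"{total} distinct assignments exceed enumeration cap {cap}")

    def rec(pool: list[int], prefix: list[int]):
        if not pool:
            yield np.array(prefix, dtype=codes.dtype)
            return
        for lab in sorted(set(pool)):
            rest = pool.copy()
            rest.remove(lab)
            yield from rec(rest, prefix + [lab])

    yield from rec(sorted(codes.tolist()), [])


def permanova(dist: DistanceMatrix, grouping: "pd.Series | list[str]",
              n_perm: int = 1000, seed: int = 0, permutations: str = "random",
              pairwise: bool = False, p_adjust: str = "bonferroni") -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F derives from the standard distance-based sum-of-squares
    decomposition (total SS = sum of squared distances / n; within-group SS
    analogously per group).  ``permutations='exhaustive'`` enumerates every
    distinct label assignment and reports the exact fraction with
    F_perm >= F_obs; the default Monte-Carlo mode uses
    ``(hits + 1) / (n_perm + 1)``.
    """
    labels = pd.Series(grouping, index=dist.ids) if not isinstance(grouping, pd.Series) \
        else grouping.loc[dist.ids]
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 samples")
    d2 = dist.values ** 2
    f_obs, r2 = _pseudo_f(d2, codes, len(uniques))

    if permutations == "exhaustive":
        hits = total = 0
        for perm in _enumerate_assignments(codes):
            f_p, _ = _pseudo_f(d2, perm, len(uniques))
            total += 1
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            f_p, _ = _pseudo_f(d2, rng.permutation(codes), len(uniques))
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        n_used = n_perm

    pw = None
    if pairwise:
        rows = []
        pairs = list(itertools.combinations(uniques, 2))
        for a, b in pairs:
            sel = labels.isin([a, b])
            ids = [i for i, s in zip(dist.ids, sel) if s]
            sub = DistanceMatrix(dist.to_frame().loc[ids, ids].to_numpy(), ids)
            res = permanova(sub, labels.loc[ids], n_perm=n_perm,
                            seed=seed, permutations=permutations)
            rows.append({"group1": a, "group2": b, "pseudo_F": res.statistic,
                         "R2": res.r2, "p_raw": res.p_value})
        pw = pd.DataFrame(rows)
        if p_adjust == "bonferroni":
            pw["p_adj"] = (pw["p_raw"] * len(pairs)).clip(upper=1.0)
        else:
            pw["p_adj"] = pw["p_raw"]
    return PermutationTestResult(statistic=float(f_obs), p_value=float(p),
                                 n_permutations=n_used, method="permanova",
                                 r2=float(r2), pairwise=pw)


def mantel(dist1: DistanceMatrix, dist2: DistanceMatrix, n_perm: int = 1000,
           seed: int = 0) -> PermutationTestResult:
    """Mantel test: Pearson correlation of lower-triangle distances.

    The null permutes the sample order of one matrix; the upper-tail p-value
    uses the ``(hits + 1) / (n_perm + 1)`` estimator.
    """
    if dist1.ids != dist2.ids:
        if set(dist1.ids) != set(dist2.ids):
            raise ValueError("sample id mismatch between matrices")
        dist2 = DistanceMatrix(dist2.to_frame().loc[dist1.ids, dist1.ids].to_numpy(),
                               dist1.ids)
    v1, v2 = dist1.condensed(), dist2.condensed()
    if v1.size != v2.size:
        raise ValueError("dimension mismatch")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = dist1.n
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        v2p = squareform(dist2.values[np.ix_(idx, idx)], checks=False)
        if np.corrcoef(v1, v2p)[0, 1] >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermutationTestResult(statistic=r_obs, p_value=p,
                                 n_permutations=n_perm, method="mantel")


def alpha_group_tests(alpha_values: pd.Series, grouping: pd.Series,
                      methods: tuple[str, ...] = ("anova", "pairwise_t_bonferroni",
                                                  "tukey_hsd", "bartlett")) -> pd.DataFrame:
    """Group comparisons of per-sample alpha diversity; one row per method."""
    from hermetia.bioconversion import compare_groups

    by_group = {g: alpha_values[grouping == g].to_numpy()
                for g in grouping.unique()}
    rows = []
    for method in methods:
        res = compare_groups(by_group, method=method)
        rows.append({"method": method, "statistic": res.statistic,
                     "p_value": res.p_value,
                     "letters": "" if res.letters is None
                     else ";".join(f"{k}:{v}" for k, v in res.letters.items())})
    return pd.DataFrame(rows)
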