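"""Indicator-species screening by a two-method consensus.

Two screens are run per taxon and their intersection reported:

* an LDA-effect-size screen: a Kruskal-Wallis filter on per-mille-normalized
  abundances followed by a one-dimensional discriminant effect magnitude
  (largest absolute between-class mean difference) averaged over bootstrap
  resamples and reported on a log10 scale;
* multi-level pattern analysis: the group-size-corrected indicator value
  IndVal.g = sqrt(specificity x fidelity) maximized over group combinations,
  with a label-permutation p-value.

A taxon is a consensus indicator when both screens call it significant *and*
agree on the associated group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hermetia.community import AbundanceTable, _enumerate_assignments

__all__ = [
    "IndicatorRecord",
    "lda_effect_size",
    "indval_multipattern",
    "consensus_indicators",
]


@dataclass
class IndicatorRecord:
    taxon: str
    kw_p: float
    lda_score: float
    indval_stat: float
    indval_p: float
    lda_group: str | None
    indval_group: str | None
    consensus: bool
    mean_rel_abund: float
    below_display_threshold: bool


def _per_mille(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.div(counts.sum(axis=1), axis=0) * 1000.0


def lda_effect_size(table: AbundanceTable, classes: pd.Series,
                    kw_alpha: float = 0.05, lda_threshold: float = 2.0,
                    n_boot: int = 30, seed: int = 0) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis p, LDA effect score and top class.

    Taxa failing the Kruskal-Wallis screen at ``kw_alpha`` get no score
    (NaN).  Surviving taxa are scored as log10 of the bootstrap-averaged
    largest between-class mean difference on per-mille-normalized
    abundances; ``significant`` marks scores >= ``lda_threshold``.
    Constant taxa take the p = 1 convention.
    """
    classes = classes.loc[table.sample_ids]
    uniques = classes.unique()
    if len(uniques) < 2:
        raise ValueError("need at least two classes")
    sizes = classes.value_counts()
    if (sizes < 3).any():
        raise ValueError("every class needs >= 3 samples")
    norm = _per_mille(table.counts)
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero((classes == c).to_numpy()) for c in uniques}

    rows = []
    for taxon in table.taxon_ids:
        x = norm[taxon].to_numpy()
        groups = [x[idx_by_class[c]] for c in uniques]
        if np.ptp(x) == 0:
            rows.append({"taxon": taxon, "kw_p": 1.0, "lda_score": math.nan,
                         "top_class": None, "significant": False})
            continue
        kw_p = float(stats.kruskal(*groups).pvalue)
        if kw_p > kw_alpha:
            rows.append({"taxon": taxon, "kw_p": kw_p, "lda_score": math.nan,
                         "top_class": None, "significant": False})
            continue
        effects = np.empty(n_boot)
        for b in range(n_boot):
            means = {}
            for c in uniques:
                idx = idx_by_class[c]
                boot = rng.choice(idx, size=idx.size, replace=True)
                means[c] = x[boot].mean()
            effects[b] = max(abs(means[a] - means[bcl])
                             for a, bcl in itertools.combinations(uniques, 2))
        effect = float(effects.mean())
        score = math.log10(max(effect, 1.0))
        top = max(uniques, key=lambda c: x[idx_by_class[c]].mean())
        rows.append({"taxon": taxon, "kw_p": kw_p, "lda_score": score,
                     "top_class": top, "significant": score >= lda_threshold})
    return pd.DataFrame(rows).set_index("taxon")


def _group_combinations(groups: list[str], allow_combinations: bool) -> list[tuple[str, ...]]:
    if not allow_combinations:
        return [(g,) for g in groups]
    combos = []
    for r in range(1, len(groups)):  # all non-trivial subsets except the full set
        combos.extend(itertools.combinations(groups, r))
    return combos


def _indval_stats(x: np.ndarray, idx_by_group: dict[str, np.ndarray],
                  combos: list[tuple[str, ...]]) -> tuple[float, int]:
    """Best IndVal.g statistic over combinations and the winning combo index."""
    group_means = {g: x[idx].mean() for g, idx in idx_by_group.items()}
    total_mean = sum(group_means.values())
    best, best_i = -1.0, 0
    for i, combo in enumerate(combos):
        # group-size-corrected specificity: sums over samples are replaced by
        # group means so unbalanced designs do not favor large groups
        a = (sum(group_means[g] for g in combo) / total_mean) if total_mean > 0 else 0.0
        idx_all = np.concatenate([idx_by_group[g] for g in combo])
        b = float((x[idx_all] > 0).mean())
        stat = math.sqrt(max(a, 0.0) * b)
        if stat > best:
            best, best_i = stat, i
    return best, best_i


def indval_multipattern(table: AbundanceTable, groups: pd.Series,
                        allow_combinations: bool = True, n_perm: int = 999,
                        seed: int = 0, permutations: str = "random") -> pd.DataFrame:
    """Multi-level pattern analysis with the IndVal.g statistic.

    For a group combination ``g``: specificity A is the (group-size
    corrected) mean abundance within ``g`` over the sum across all groups,
    fidelity B the fraction of ``g``'s samples where the taxon is present
    (count > 0); stat = sqrt(A x B), maximized over all non-trivial subsets
    of groups (the full set excluded).  p-values permute sample labels;
    ``permutations='exhaustive'`` enumerates all distinct assignments for
    small designs.
    """
    groups = groups.loc[table.sample_ids]
    labels = list(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (groups.value_counts() == 0).any():
        raise ValueError("empty group")
    combos = _group_combinations(labels, allow_combinations)
    codes, uniques = pd.factorize(groups)
    idx_by_group = {g: np.flatnonzero((groups == g).to_numpy()) for g in labels}

    perms: list[np.ndarray] = []
    if permutations == "exhaustive":
        perms = list(_enumerate_assignments(codes))
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(codes) for _ in range(n_perm)]

    rows = []
    for taxon in table.taxon_ids:
        x = table.counts[taxon].to_numpy(dtype=float)
        stat_obs, best_i = _indval_stats(x, idx_by_group, combos)
        hits = 0
        for perm in perms:
            perm_idx = {g: np.flatnonzero(perm == k)
                        for k, g in enumerate(uniques)}
            stat_p, _ = _indval_stats(x, perm_idx, combos)
            if stat_p >= stat_obs - 1e-12:
                hits += 1
        if permutations == "exhaustive":
            p = hits / len(perms)
        else:
            p = (hits + 1) / (len(perms) + 1)
        rows.append({"taxon": taxon, "indval_stat": float(stat_obs),
                     "indval_p": float(p),
                     "group": "+".join(combos[best_i])})
    return pd.DataFrame(rows).set_index("taxon")


def consensus_indicators(lefse: pd.DataFrame, indval: pd.DataFrame,
                         table: AbundanceTable | None = None,
                         indval_alpha: float = 0.05,
                         report_min_rel_abund: float = 0.01) -> list[IndicatorRecord]:
    """Join the two screens into consensus records.

    Consensus requires significance in both methods *and* agreement on the
    associated group (the LDA top class must be contained in the IndVal
    group combination).  Records below ``report_min_rel_abund`` are retained
    but flagged as below the display threshold.
    """
    if set(lefse.index) != set(indval.index):
        raise ValueError("taxon id mismatch between the two screens")
    mean_rel = (table.relative().mean(axis=0) if table is not None
                else pd.Series(math.nan, index=lefse.index))
    records = []
    for taxon in lefse.index:
        le, iv = lefse.loc[taxon], indval.loc[taxon]
        iv_sig = iv["indval_p"] <= indval_alpha
        groups_iv = str(iv["group"]).split("+")
        same_group = le["top_class"] is not None and le["top_class"] in groups_iv
        consensus = bool(le["significant"] and iv_sig and same_group)
        rel = float(mean_rel.get(taxon, math.nan))
        records.append(IndicatorRecord(
            taxon=taxon, kw_p=float(le["kw_p"]),
            lda_score=float(le["lda_score"]),
            indval_stat=float(iv["indval_stat"]), indval_p=float(iv["indval_p"]),
            lda_group=le["top_class"], indval_group=str(iv["group"]),
            consensus=consensus, mean_rel_abund=rel,
            below_display_threshold=bool(rel < report_min_rel_abund)
            if not math.isnan(rel) else False,
        ))
    return records


def indicator_table(records: list[IndicatorRecord]) -> pd.DataFrame:
    """Flat report table of indicator records (one row per taxon)."""
    return pd.DataFrame([r.__dict__ for r in records]).set_index("taxon")
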