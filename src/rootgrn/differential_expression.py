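"""Significance analysis of microarrays (SAM) for two-class comparisons.

The SAM statistic for gene *i* is the moderated mean difference

    d(i) = (mean2(i) - mean1(i)) / (s(i) + s0)

with the pooled scatter

    s(i) = sqrt( (1/n1 + 1/n2) / (n1 + n2 - 2) * (SS1(i) + SS2(i)) )

and the exchangeability factor s0 chosen to stabilise small variances.
False-discovery-rate q-values come from permuting class labels: for each
|d| cutoff the median number of permuted scores exceeding it, scaled by an
estimate of the null proportion pi0, is divided by the observed count; a
gene's q is the smallest such FDR at any cutoff it passes.

"Multi-way" comparisons (several genotypes pooled into one class, as in the
hairy-vs-hairless arrangement) are handled simply by listing all pooled
samples in one class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from rootgrn.core_data import ExpressionMatrix

S0Mode = Literal["tusher_cv_min", "fixed_percentile"]


@dataclass
class SamConfig:
    """SAM tuning knobs.

    ``s0_mode='tusher_cv_min'`` picks s0 among percentile candidates of s to
    minimise the coefficient of variation of the MAD of d across s-quantile
    windows (the original SAM recipe); ``'fixed_percentile'`` takes the
    ``s0_percentile`` quantile of s directly.  ``s0_fixed`` overrides both
    (s0_fixed=0 gives the plain pooled-scatter t-like statistic used in the
    worked examples).  Label permutations are exhaustive whenever the number
    of distinct class-label splits is at most ``exhaustive_max``, otherwise
    ``n_permutations`` balanced splits are drawn.
    """

    s0_mode: S0Mode = "tusher_cv_min"
    s0_percentile: float = 0.5
    s0_fixed: float | None = None
    n_permutations: int = 200
    exhaustive_max: int = 1024
    pi0: Literal["one", "estimate"] = "one"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s0_percentile <= 1.0:
            raise ValueError("s0_percentile must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class SamResult:
    gene_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    fc: np.ndarray  # linear-scale ratio class2 / class1
    s0: float
    q: np.ndarray | None = None
    pi0: float = 1.0
    n_permutations_used: int = 0
    exhaustive: bool = False
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene(self, gene_id: str) -> dict[str, float]:
        i = self._index[gene_id]
        out = {"d": float(self.d[i]), "s": float(self.s[i]), "fc": float(self.fc[i])}
        if self.q is not None:
            out["q"] = float(self.q[i])
        return out

    def q_of(self, gene_id: str) -> float:
        if self.q is None:
            raise ValueError("q-values not computed; run estimate_fdr")
        return float(self.q[self._index[gene_id]])

    def to_frame(self):
        import pandas as pd

        cols = {"d": self.d, "s": self.s, "fc": self.fc}
        if self.q is not None:
            cols["q"] = self.q
        return pd.DataFrame(cols, index=pd.Index(self.gene_ids, name="gene_id"))


def _class_matrices(
    expr: ExpressionMatrix, class1: Sequence[str], class2: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    set1, set2 = set(class1), set(class2)
    if set1 & set2:
        raise ValueError(f"classes overlap: {sorted(set1 & set2)}")
    if len(set1) < 2 or len(set2) < 2:
        raise ValueError("each class needs at least 2 samples")
    return expr.sample_columns(list(class1)), expr.sample_columns(list(class2))


def _d_stat(
    x1: np.ndarray, x2: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (d, s, r) for genes x samples blocks x1 (class1), x2 (class2)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * (ss1 + ss2))
    r = m2 - m1
    return r / (s + s0), s, r


def _choose_s0(r: np.ndarray, s: np.ndarray, cfg: SamConfig) -> float:
    if cfg.s0_fixed is not None:
        return float(cfg.s0_fixed)
    if cfg.s0_mode == "fixed_percentile":
        return float(np.quantile(s, cfg.s0_percentile))
    # Tusher CV-minimisation: candidates are percentiles of s; for each,
    # compute the MAD of d within s-quantile windows and minimise the
    # coefficient of variation of those MADs.
    n = len(s)
    order = np.argsort(s, kind="stable")
    n_win = max(2, min(100, n // 5))
    windows = np.array_split(order, n_win)
    candidates = np.quantile(s, np.linspace(0.0, 1.0, 21))
    best_s0, best_cv = float(candidates[0]), math.inf
    for s0c in candidates:
        d = r / (s + s0c)
        mads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) for w in windows]
        )
        mu = mads.mean()
        if mu == 0:
            continue
        cv = mads.std() / mu
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(s0c)
    return best_s0


def sam_scores(
    expr: ExpressionMatrix,
    class1: Sequence[str],
    class2: Sequence[str],
    cfg: SamConfig | None = None,
) -> SamResult:
    """SAM d, pooled scatter s and linear fold change class2/class1."""
    cfg = cfg or SamConfig()
    x1, x2 = _class_matrices(expr, class1, class2)
    _, s, r = _d_stat(x1, x2, 0.0)
    s0 = _choose_s0(r, s, cfg)
    d = r / (s + s0)
    return SamResult(list(expr.gene_ids), d, s, np.power(2.0, r), s0)


def fold_change(
    expr: ExpressionMatrix, class1: Sequence[str], class2: Sequence[str]
) -> np.ndarray:
    """Per-gene linear ratio 2^(mean2 - mean1), as reported in the tables."""
    x1, x2 = _class_matrices(expr, class1, class2)
    return np.power(2.0, x2.mean(axis=1) - x1.mean(axis=1))


# ---------------------------------------------------------------------------
# permutation FDR


def _all_splits(n: int, n1: int) -> list[tuple[int, ...]]:
    return list(itertools.combinations(range(n), n1))


def _balanced_splits(
    n1: int, n2: int, k: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """k random label splits with (near-)equal representation of the original
    classes in each permuted class."""
    n = n1 + n2
    target = n1 * n1 / n
    lo, hi = math.floor(target), math.ceil(target)
    out = []
    for _ in range(k):
        k1 = int(rng.integers(lo, hi + 1))
        k1 = min(max(k1, max(0, n1 - n2)), n1)  # feasibility clip
        from1 = rng.choice(n1, size=k1, replace=False)
        from2 = rng.choice(n2, size=n1 - k1, replace=False) + n1
        out.append(tuple(sorted(np.concatenate([from1, from2]).tolist())))
    return out


def estimate_fdr(
    expr: ExpressionMatrix,
    class1: Sequence[str],
    class2: Sequence[str],
    cfg: SamConfig | None = None,
) -> SamResult:
    """SAM scores plus permutation-based FDR q-values.

    The permuted statistics reuse the s0 chosen on the observed labelling.
    q-values are clipped to [0, 1] and monotonised (cumulative minimum over
    genes ordered by decreasing |d|), so q is non-increasing in |d|.
    """
    cfg = cfg or SamConfig()
    res = sam_scores(expr, class1, class2, cfg)
    x = np.hstack(_class_matrices(expr, class1, class2))
    n1, n2 = len(class1), len(class2)
    n = n1 + n2

    total = math.comb(n, n1)
    if total <= 1:
        raise ValueError("degenerate class sizes: no label permutations exist")
    rng = np.random.default_rng(cfg.seed)
    if total <= cfg.exhaustive_max:
        splits = _all_splits(n, n1)
        exhaustive = True
    else:
        splits = _balanced_splits(n1, n2, cfg.n_permutations, rng)
        exhaustive = False

    all_idx = np.arange(n)
    d_perm = np.empty((len(splits), expr.n_genes))
    for p, c1_idx in enumerate(splits):
        c1 = np.array(c1_idx)
        c2 = np.setdiff1d(all_idx, c1, assume_unique=True)
        d_perm[p], _, _ = _d_stat(x[:, c1], x[:, c2], res.s0)

    abs_d = np.abs(res.d)
    order = np.argsort(abs_d, kind="stable")  # ascending
    cutoffs = abs_d[order]
    m = len(cutoffs)
    # observed count of |d| >= cutoff_i  (cutoffs ascending)
    obs_counts = m - np.searchsorted(cutoffs, cutoffs, side="left")
    # median permuted count above each cutoff
    abs_perm = np.sort(np.abs(d_perm), axis=1)
    perm_counts = abs_perm.shape[1] - np.array(
        [np.searchsorted(row, cutoffs, side="left") for row in abs_perm]
    )
    med_null = np.median(perm_counts, axis=0)

    pi0 = 1.0
    if cfg.pi0 == "estimate":
        lo_q, hi_q = np.quantile(d_perm, [0.25, 0.75])
        inside = np.sum((res.d >= lo_q) & (res.d <= hi_q))
        pi0 = min(1.0, float(inside) / (0.5 * m)) if m else 1.0

    fdr = np.clip(pi0 * med_null / np.maximum(obs_counts, 1), 0.0, 1.0)
    # monotonise: q at a cutoff is the best FDR at any cutoff the gene passes
    # (all cutoffs <= |d_i|, i.e. the cumulative min in ascending-|d| order)
    q_sorted = np.minimum.accumulate(fdr)
    q = np.empty(m)
    q[order] = q_sorted

    res.q = q
    res.pi0 = pi0
    res.n_permutations_used = len(splits)
    res.exhaustive = exhaustive
    return res
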