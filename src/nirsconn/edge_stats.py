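"""Paired pre/post statistics on connectivity edges.

Each of the 231 channel-pair edges is tested with a two-sided paired t-test
on per-subject raw correlation values (pre minus post), and the 231 p-values
are corrected with the Benjamini-Hochberg step-up procedure at q = 0.05.
Edges whose paired differences have zero variance are flagged as degenerate
and excluded from the correction rather than assigned an artificial p-value.
The group-level mean-correlation comparison applies the same paired t-test
to per-subject mean-COR scalars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix, mean_cor_scalar
from .errors import DegenerateTestError, InvalidInputError
from .montage import roi_of_index


@dataclass
class PairedEdgeSamples:
    """subjects x edges matrices of pre and post edge values.

    Edges enumerate the strict upper triangle in row-major order;
    ``edge_index`` lists the corresponding 0-based (i, j) pairs with i < j.
    """

    pre: np.ndarray
    post: np.ndarray
    edge_index: list[tuple[int, int]]
    group_label: str = ""

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape:
            raise InvalidInputError("pre and post must have the same shape (paired design)")
        if self.pre.shape[1] != len(self.edge_index):
            raise InvalidInputError("edge_index length must match the edge axis")

    @classmethod
    def from_matrices(cls, pre: list[ConnectivityMatrix], post: list[ConnectivityMatrix],
                      group_label: str = "") -> "PairedEdgeSamples":
        if len(pre) != len(post) or not pre:
            raise InvalidInputError("need equal, non-empty pre and post matrix lists")
        n = pre[0].n_channels
        iu = np.triu_indices(n, k=1)
        edge_index = list(zip(iu[0].tolist(), iu[1].tolist()))
        pre_m = np.stack([m.values[iu] for m in pre])
        post_m = np.stack([m.values[iu] for m in post])
        return cls(pre_m, post_m, edge_index, group_label=group_label)

    @property
    def n_subjects(self) -> int:
        return self.pre.shape[0]

    @property
    def n_edges(self) -> int:
        return self.pre.shape[1]


@dataclass
class EdgeTestResult:
    """Per-edge paired t statistics with BH-FDR significance flags."""

    t: np.ndarray
    p: np.ndarray
    q_significant: np.ndarray
    degenerate: np.ndarray
    edge_index: list[tuple[int, int]]
    alpha: float = 0.05
    fdr_q: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        """Tidy results table (edge label, ROI pair, t, p, FDR flag), sorted by p."""
        rows = []
        for k, (i, j) in enumerate(self.edge_index):
            try:
                roi_pair = "-".join(sorted((roi_of_index(i + 1), roi_of_index(j + 1))))
            except Exception:
                roi_pair = ""
            rows.append({
                "edge": f"CH{i + 1:02d}-CH{j + 1:02d}",
                "roi_pair": roi_pair,
                "t": self.t[k],
                "p": self.p[k],
                "fdr_significant": bool(self.q_significant[k]),
                "degenerate": bool(self.degenerate[k]),
            })
        return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on d = pre - post, n-1 degrees of freedom.

    Identical pre/post gives (0, 1); zero-variance non-zero-mean differences
    raise DegenerateTestError (never a silent p = 0).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InvalidInputError("paired vectors must be 1-D and equal length")
    n = pre.size
    if n < 2:
        raise InvalidInputError("need at least 2 pairs")
    d = pre - post
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise DegenerateTestError("constant non-zero paired differences: t is unbounded")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(pvals)) or pvals.min() < 0 or pvals.max() > 1:
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def edgewise_paired_test(samples: PairedEdgeSamples, q: float = 0.05,
                         alpha: float = 0.05) -> EdgeTestResult:
    """Per-edge paired t-tests with BH-FDR across all non-degenerate edges."""
    if samples.n_subjects < 2:
        raise InvalidInputError("need at least 2 subjects")
    d = samples.pre - samples.post
    n = samples.n_subjects
    sd = d.std(axis=0, ddof=1)
    mean = d.mean(axis=0)
    degenerate = sd == 0

    t = np.zeros(samples.n_edges)
    p = np.ones(samples.n_edges)
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * sstats.t.sf(np.abs(t[ok]), df=n - 1)
    # zero-variance, zero-mean edges are exact ties: t=0, p=1, not degenerate
    exact_null = degenerate & np.isclose(mean, 0.0)
    degenerate = degenerate & ~exact_null

    q_sig = np.zeros(samples.n_edges, dtype=bool)
    mask = ~degenerate
    if mask.any():
        q_sig[mask] = fdr_bh(p[mask], q=q)
    return EdgeTestResult(t=t, p=p, q_significant=q_sig, degenerate=degenerate,
                          edge_index=samples.edge_index, alpha=alpha, fdr_q=q)


def mean_cor_paired_test(pre_mats: list[ConnectivityMatrix],
                         post_mats: list[ConnectivityMatrix]) -> tuple[float, float]:
    """Paired t-test on per-subject mean-COR scalars (group-level comparison)."""
    pre = np.array([mean_cor_scalar(m) for m in pre_mats])
    post = np.array([mean_cor_scalar(m) for m in post_mats])
    return paired_t(pre, post)
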