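"""Block-average error analysis and the normality-gated two-group test.

Trajectory observables are serially correlated, so the naive SD/sqrt(n)
underestimates the error of the mean.  The block-averages method cuts the
series into contiguous blocks and takes the SD of block means; once blocks
are longer than the correlation time the implied standard error
(block SD / sqrt(n_blocks)) stops growing, and the plateau value is the
honest error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

from .core_model import FilamentEnsemble

__all__ = ["BlockResult", "GroupComparison", "trim_equilibration",
           "block_average", "compare_groups"]


@dataclass
class BlockResult:
    mean: float
    block_sd: float          # SD of block means
    block_size: int
    n_blocks: int
    plateau_found: bool

    @property
    def se_mean(self) -> float:
        """Standard error of the series mean implied by the blocking."""
        return self.block_sd / np.sqrt(self.n_blocks)


@dataclass
class GroupComparison:
    test_used: Literal["t", "mann-whitney"]
    p_value: float
    normality_p_a: float
    normality_p_b: float
    direction: Literal["a>b", "a<b", "ns"]
    statistic: float = float("nan")


def trim_equilibration(ensemble: FilamentEnsemble, discard_until: float) -> FilamentEnsemble:
    """Drop frames with time <= discard_until (ns); keeps the production window."""
    keep = ensemble.times > discard_until
    if not np.any(keep):
        raise ValueError(
            f"discarding up to {discard_until} ns removes all "
            f"{ensemble.n_frames} frames (last time {ensemble.times[-1]} ns)")
    out = FilamentEnsemble(ensemble.coords[keep], ensemble.residue_ids,
                           ensemble.frame_interval, ensemble.label,
                           ensemble.times[keep])
    out.trim_window = (float(discard_until), float(ensemble.times[-1]))
    return out


def _block_stats(x: np.ndarray, b: int) -> tuple[float, float, int]:
    n_blocks = len(x) // b
    blocks = x[: n_blocks * b].reshape(n_blocks, b).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=1)), n_blocks


def block_average(series, block_size: int | str = "auto") -> BlockResult:
    """Block-average a scalar series.

    With a fixed ``block_size`` the series is cut into floor(n/b) contiguous
    blocks.  In ``auto`` mode the block size is doubled from 1 until the
    implied standard error of the mean changes by < 10% across two
    successive doublings (plateau) or fewer than 4 blocks remain.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError("series must contain at least 4 values")
    if block_size == "auto":
        ses = []
        results = []
        b = 1
        while len(x) // b >= 4:
            mean, bsd, nb = _block_stats(x, b)
            results.append(BlockResult(mean, bsd, b, nb, False))
            ses.append(bsd / np.sqrt(nb))
            if len(ses) >= 3:
                prev, cur = ses[-2], ses[-1]
                prev2 = ses[-3]
                if (prev2 > 0 and cur > 0
                        and abs(prev - prev2) / prev2 < 0.10
                        and abs(cur - prev) / prev < 0.10):
                    res = results[-1]
                    res.plateau_found = True
                    return res
            b *= 2
        res = results[-1]
        if res.block_sd == 0.0 and all(s == 0 for s in ses):
            res.plateau_found = True  # constant series: trivially converged
        return res
    b = int(block_size)
    if b < 1 or b > len(x) // 2:
        raise ValueError(f"block_size {b} must lie in 1..n/2 ({len(x) // 2})")
    mean, bsd, nb = _block_stats(x, b)
    return BlockResult(mean, bsd, b, nb, True)


def compare_groups(a, b, alpha_normality: float = 0.05) -> GroupComparison:
    """Two-sided two-group comparison with a normality gate.

    Each sample is tested for normality with a Kolmogorov-Smirnov test
    against a normal with the sample's own mean and SD; if either sample
    fails (p < alpha_normality) the Mann-Whitney rank-sum test is used,
    otherwise the unpaired two-sample t-test.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample must contain at least 3 values")

    def ks_norm_p(x: np.ndarray) -> float:
        sd = x.std(ddof=1)
        if sd == 0:
            return 0.0  # degenerate sample: certainly not normal
        return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)

    pa, pb = ks_norm_p(a), ks_norm_p(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return GroupComparison("mann-whitney", 1.0, pa, pb, "ns", float("nan"))
    if pa < alpha_normality or pb < alpha_normality:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    else:
        res = sps.ttest_ind(a, b)
        test = "t"
    p = float(res.pvalue)
    if p < 0.05:
        direction = "a>b" if a.mean() > b.mean() else "a<b"
    else:
        direction = "ns"
    return GroupComparison(test, p, pa, pb, direction, float(res.statistic))
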