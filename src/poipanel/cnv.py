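"""Amplicon-coverage CNV calling and pathogenicity banding.

The caller mirrors the classical amplicon workflow: per-sample coverage is
scaled to equal totals, divided by a median baseline built from controls,
GC-corrected by bin-median scaling, and log2-transformed.  Sample noise is
summarized by MAPD (median absolute pairwise difference of genome-adjacent
log2 ratios); noisy samples (MAPD >= 0.4) are refused unless forced.
Ploidy is decoded by a Viterbi pass over integer copy-number states with
Gaussian emissions centred on log2(k/2) (k = 0 floored at 0.05 so the mean
stays finite), per-sample sigma estimated from MAPD, and a strongly sticky
transition matrix.  Segment confidence is the summed log10 likelihood ratio
of the called state against diploid, so the significance threshold (> 10)
reads as ten orders of magnitude.

Structural-variant pathogenicity uses the X-CNV meta-voting prediction
(MVP) bands — the only published band set with numeric boundaries;
StrVCTVRE and CADD-SV are reported alongside but never override the band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import CNVSegment, QpcrMeasurement, SVScoreSet, SampleNoise

__all__ = [
    "CNVConfig",
    "build_baseline",
    "normalize_and_correct_gc",
    "compute_mapd",
    "viterbi",
    "call_cnv_hmm",
    "filter_and_flag",
    "tier_sv_scores",
    "qpcr_relative_quantity",
    "compare_qpcr_groups",
    "MAPD_TO_SIGMA",
]

#: For i.i.d. Gaussian log2 ratios, MAPD = sigma * sqrt(2) * PHI^-1(0.75);
#: the conventional per-sample scale estimate inverts MAPD with the 1.349
#: constant (2 * PHI^-1(0.75)).
MAPD_TO_SIGMA = 1.349


@dataclass(frozen=True)
class CNVConfig:
    """Tunables of the CNV caller."""

    mapd_max: float = 0.4
    confidence_min: float = 10.0  # log10 LR vs diploid, strict >
    focal_max_len: int = 3_000_000  # bp, strict <
    ploidy_states: tuple[int, ...] = (0, 1, 2, 3, 4)
    hmm_stay_prob: float = 1.0 - 1e-4
    gc_bin_width: float = 0.05
    min_gc_bin_count: int = 5
    zero_state_floor: float = 0.05  # pseudo-copy for the homozygous-loss mean
    sigma_floor: float = 1e-3
    log2_ratio_min: float = -6.0  # clip for zero-coverage amplicons

    def __post_init__(self) -> None:
        if self.mapd_max <= 0:
            raise ValueError("mapd_max must be > 0")
        if 2 not in self.ploidy_states:
            raise ValueError("diploid state must be among ploidy_states")
        if not (0 < self.hmm_stay_prob < 1):
            raise ValueError("hmm_stay_prob must be in (0, 1)")


def build_baseline(control_matrix: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Per-amplicon median of sample-normalized control coverage.

    ``control_matrix`` is amplicon x sample read counts (>= 2 samples, each
    with positive total).  Each sample is scaled to unit total, and the
    baseline is the row-wise median.  Amplicons with zero baseline are
    flagged for downstream exclusion and returned separately.
    """
    if control_matrix.shape[1] < 2:
        raise ValueError("baseline requires >= 2 control samples")
    totals = control_matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"control sample(s) with zero total reads: {bad}")
    normalized = control_matrix / totals
    baseline = normalized.median(axis=1)
    excluded = list(baseline.index[baseline <= 0])
    if excluded:
        warnings.warn(
            f"build_baseline: {len(excluded)} amplicon(s) with zero coverage "
            "in all controls excluded"
        )
        baseline = baseline[baseline > 0]
    return baseline, excluded


def _gc_bins(gc: pd.Series, width: float, min_count: int) -> pd.Series:
    bins = np.floor(gc / width).astype(int)
    counts = bins.value_counts()
    small = [b for b in counts.index if counts[b] < min_count]
    big = [b for b in counts.index if counts[b] >= min_count]
    if small and big:
        warnings.warn(f"gc correction: merging {len(small)} sparse bin(s) into neighbors")
        remap = {b: min(big, key=lambda ref: abs(ref - b)) for b in small}
        bins = bins.replace(remap)
    return bins


def normalize_and_correct_gc(
    sample_counts: pd.Series,
    baseline: pd.Series,
    gc_fraction: pd.Series,
    cfg: CNVConfig | None = None,
) -> pd.Series:
    """Per-amplicon GC-corrected log2 coverage ratios.

    ratio_i = (count_i / total) / baseline_i, then each ratio is divided by
    the median ratio of its GC bin (width 0.05; sparse bins merged into the
    nearest populated bin) and log2-transformed.  A sample identical to the
    baseline maps to all-zero ratios.
    """
    cfg = cfg or CNVConfig()
    shared = baseline.index.intersection(sample_counts.index)
    counts = sample_counts.loc[shared].astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero total reads over baseline amplicons")
    ratio = (counts / total) / baseline.loc[shared]
    bins = _gc_bins(gc_fraction.loc[shared], cfg.gc_bin_width, cfg.min_gc_bin_count)
    bin_median = ratio.groupby(bins).median()
    corrected = ratio / bins.map(bin_median)
    log2r = np.log2(corrected.clip(lower=2.0**cfg.log2_ratio_min))
    return log2r


def compute_mapd(
    log2_ratios: pd.Series,
    panel: pd.DataFrame,
    sample_id: str = "",
    cfg: CNVConfig | None = None,
) -> SampleNoise:
    """Median absolute pairwise difference of genome-adjacent log2 ratios.

    Adjacency is genome-position order within each chromosome;
    cross-chromosome pairs are excluded.  Eligible iff MAPD < 0.4.
    """
    cfg = cfg or CNVConfig()
    ordered = _order_by_position(log2_ratios, panel)
    if len(ordered) < 2:
        raise ValueError("MAPD requires >= 2 amplicons")
    diffs = []
    for _, group in ordered.groupby("chrom", sort=False):
        values = group["log2r"].to_numpy()
        if len(values) >= 2:
            diffs.append(np.abs(np.diff(values)))
    if not diffs:
        raise ValueError("MAPD requires >= 2 amplicons on one chromosome")
    mapd = float(np.median(np.concatenate(diffs)))
    return SampleNoise(sample_id=sample_id, mapd=mapd, eligible=mapd < cfg.mapd_max)


def _order_by_position(log2_ratios: pd.Series, panel: pd.DataFrame) -> pd.DataFrame:
    indexed = panel.set_index("amplicon_id") if "amplicon_id" in panel.columns else panel
    df = indexed.loc[log2_ratios.index, ["chrom", "start", "end"]].copy()
    df["log2r"] = log2_ratios
    return df.sort_values(["chrom", "start"], kind="mergesort")


def viterbi(
    observations: np.ndarray,
    means: np.ndarray,
    sigma: float,
    stay_prob: float,
) -> np.ndarray:
    """Most likely state path under Gaussian emissions and a sticky chain.

    Uniform initial distribution; off-diagonal transition mass is spread
    uniformly over the other states.  Returns state indices.
    """
    obs = np.asarray(observations, dtype=float)
    n_states = len(means)
    n = len(obs)
    log_stay = math.log(stay_prob)
    log_switch = math.log((1.0 - stay_prob) / (n_states - 1))
    # emission log-likelihoods, (n, k)
    emit = -0.5 * ((obs[:, None] - means[None, :]) / sigma) ** 2 - math.log(
        sigma * math.sqrt(2 * math.pi)
    )
    score = emit[0] - math.log(n_states)
    backptr = np.zeros((n, n_states), dtype=int)
    trans = np.full((n_states, n_states), log_switch)
    np.fill_diagonal(trans, log_stay)
    for t in range(1, n):
        cand = score[:, None] + trans  # (from, to)
        backptr[t] = np.argmax(cand, axis=0)
        score = cand[backptr[t], np.arange(n_states)] + emit[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return path


def call_cnv_hmm(
    log2_ratios: pd.Series,
    panel: pd.DataFrame,
    cfg: CNVConfig | None = None,
    sample_id: str = "",
    force: bool = False,
) -> list[CNVSegment]:
    """Decode per-amplicon ploidy and merge runs into segments.

    Refuses samples failing the MAPD gate unless ``force``.  Segments span
    from the first amplicon's start to the last amplicon's end and partition
    the amplicon sequence; neutral (diploid) segments are emitted too, with
    ``change == 'neutral'``.
    """
    cfg = cfg or CNVConfig()
    noise = compute_mapd(log2_ratios, panel, sample_id=sample_id, cfg=cfg)
    if not noise.eligible and not force:
        raise ValueError(
            f"sample {sample_id!r} ineligible (MAPD {noise.mapd:.3f} >= "
            f"{cfg.mapd_max}); pass force=True to override"
        )
    sigma = max(noise.mapd / MAPD_TO_SIGMA, cfg.sigma_floor)
    states = np.asarray(cfg.ploidy_states)
    means = np.log2(np.maximum(states, cfg.zero_state_floor) / 2.0)

    ordered = _order_by_position(log2_ratios, panel)
    segments: list[CNVSegment] = []
    diploid_idx = int(np.where(states == 2)[0][0])
    for chrom, group in ordered.groupby("chrom", sort=False):
        obs = group["log2r"].to_numpy()
        path = viterbi(obs, means, sigma, cfg.hmm_stay_prob)
        # per-amplicon log10 LR of called state vs diploid
        loglr = (
            stats.norm.logpdf(obs, loc=means[path], scale=sigma)
            - stats.norm.logpdf(obs, loc=means[diploid_idx], scale=sigma)
        ) / math.log(10)
        boundaries = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(path)]])
        for lo, hi in zip(starts, ends):
            segments.append(
                CNVSegment(
                    sample_id=sample_id,
                    chrom=str(chrom),
                    start=int(group["start"].iloc[lo]),
                    end=int(group["end"].iloc[hi - 1]),
                    ploidy=int(states[path[lo]]),
                    confidence=float(loglr[lo:hi].sum()),
                    n_amplicons=int(hi - lo),
                )
            )
    return segments


def filter_and_flag(
    segments: list[CNVSegment], cfg: CNVConfig | None = None
) -> list[CNVSegment]:
    """Drop low-confidence non-neutral segments; set the focal flag.

    Significance requires confidence strictly greater than the threshold;
    focal means length strictly below 3 Mb.
    """
    cfg = cfg or CNVConfig()
    kept = []
    for seg in segments:
        if seg.change != "neutral" and not seg.confidence > cfg.confidence_min:
            continue
        seg.focal = seg.length < cfg.focal_max_len
        kept.append(seg)
    return kept


def tier_sv_scores(scores: SVScoreSet) -> str:
    """Band a CNV by its MVP score.

    [0.46, 0.76] -> likely_pathogenic; [0.16, 0.46) -> uncertain;
    [0.14, 0.16) -> likely_benign; anything else is reported as
    ``out_of_band`` rather than extrapolated beyond the published bands.
    A missing MVP yields ``undetermined``.
    """
    mvp = scores.mvp
    if mvp is None or (isinstance(mvp, float) and math.isnan(mvp)):
        return "undetermined"
    if 0.46 <= mvp <= 0.76:
        return "likely_pathogenic"
    if 0.16 <= mvp < 0.46:
        return "uncertain"
    if 0.14 <= mvp < 0.16:
        return "likely_benign"
    return "out_of_band"


def qpcr_relative_quantity(m: QpcrMeasurement) -> float:
    """Comparative-Ct relative quantity 2^-ddCt against the calibrator."""
    dct_sample = m.target_ct - m.reference_ct
    dct_calibrator = m.calibrator_target_ct - m.calibrator_reference_ct
    return 2.0 ** -(dct_sample - dct_calibrator)


def compare_qpcr_groups(dct_a, dct_b) -> tuple[float, float]:
    """Two-sample t-test on per-replicate delta-Ct values; returns (t, p)."""
    t_stat, p_value = stats.ttest_ind(np.asarray(dct_a), np.asarray(dct_b))
    return float(t_stat), float(p_value)
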