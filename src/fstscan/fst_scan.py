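"""Per-SNP Nei F_ST scan with LOWESS smoothing and control-chart outliers.

The analytical core of the package.  For each SNP with group allele
frequencies p1 (CE) and p2 (HE):

    p_bar = (p1 + p2) / 2
    H_T   = 2 * p_bar * (1 - p_bar)
    H_S   = (2*p1*(1-p1) + 2*p2*(1-p2)) / 2
    F_ST  = (H_T - H_S) / H_T

i.e. Nei's G_ST with equal subpopulation weights (a sample-size-weighted
pooled frequency is available behind ``weighting="size"``).  Raw values are
then smoothed per chromosome with a locally weighted degree-1 regression
whose span is 20 / (markers on the chromosome), so every fit window holds 20
SNPs; outliers are flagged per chromosome by an upper one-sided Shewhart
rule (smoothed value > mean + 3*SD), and consecutive outliers within 1 Mb
are merged into selection signatures.

SNPs whose F_ST is undefined (pooled heterozygosity zero, or a group with no
calls) are excluded before smoothing, so fit neighborhoods span informative
markers only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_grouping import GROUP_COLD, GROUP_HOT
from .io_formats import MISSING, GenotypeDataset


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the differentiation scan.

    span_snps:
        SNPs per local-regression window; the per-chromosome span fraction is
        ``span_snps / n`` capped at 1.
    sd_multiplier:
        Control-chart width in standard deviations (upper one-sided).
    sd_estimator:
        ``"sample"`` for the plain n-1 standard deviation of smoothed values,
        ``"moving_range"`` for the individuals-chart estimate
        ``mean(|x_i - x_{i-1}|) / 1.128``.
    signature_max_gap_bp:
        Consecutive outlier SNPs at most this far apart merge into one
        selection signature.
    weighting:
        ``"equal"`` (Nei's canonical pooled frequency) or ``"size"``
        (sample-size-weighted pooled frequency and H_S).
    """

    span_snps: int = 20
    sd_multiplier: float = 3.0
    sd_estimator: str = "sample"
    signature_max_gap_bp: int = 1_000_000
    weighting: str = "equal"

    def __post_init__(self):
        if self.span_snps < 1:
            raise ValueError("span_snps must be >= 1")
        if self.sd_estimator not in {"sample", "moving_range"}:
            raise ValueError(f"unknown sd_estimator {self.sd_estimator!r}")
        if self.weighting not in {"equal", "size"}:
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass
class OutlierCall:
    """Per-chromosome control-chart summary."""

    chromosome: int
    mean_smoothed: float
    sd_smoothed: float
    upper_limit: float
    flagged_snp_ids: list = field(default_factory=list)


@dataclass
class ScanResult:
    """Scan table, signature table and per-chromosome chart metadata."""

    scan_table: pd.DataFrame
    signatures: pd.DataFrame
    outlier_calls: list


# ---------------------------------------------------------------------------
# group frequencies and the Nei metric
# ---------------------------------------------------------------------------

def group_allele_frequencies(dataset: GenotypeDataset, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP allele-b frequencies and non-missing counts for CE and HE.

    *assignments* is the output of :func:`fstscan.env_grouping.assign_groups`;
    UNASSIGNED samples are ignored.  SNPs where a group has no calls get
    ``defined=False`` (frequency NaN) and are excluded from smoothing later.
    """
    group_of = dict(zip(assignments["sample_id"], assignments["group"]))
    labels = dataset.samples["sample_id"].map(group_of)
    mask1 = (labels == GROUP_COLD).to_numpy()
    mask2 = (labels == GROUP_HOT).to_numpy()
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise ValueError("both CE and HE groups need at least one sample")

    def freqs(mask):
        sub = dataset.calls[mask]
        obs = sub != MISSING
        n = obs.sum(axis=0)
        count_b = np.where(obs, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = count_b / (2.0 * n)
        return p, n

    p1, n1 = freqs(mask1)
    p2, n2 = freqs(mask2)
    out = dataset.markers[["snp_id", "chromosome", "position"]].copy()
    out["p1"], out["n1"] = p1, n1
    out["p2"], out["n2"] = p2, n2
    out["defined"] = (n1 > 0) & (n2 > 0)
    return out


def nei_fst(p1, p2, n1=None, n2=None, weighting: str = "equal"):
    """Nei fixation index between two groups from allele frequencies.

    Returns ``(h_t, h_s, fst)``; each argument may be a scalar or array.
    With ``weighting="size"`` the pooled frequency and H_S use sample-size
    weights (requires n1, n2).  F_ST is NaN where H_T = 0 (monomorphic pooled
    frequency).  The statistic is invariant to swapping allele coding
    (p -> 1-p in both groups).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if weighting == "size":
        if n1 is None or n2 is None:
            raise ValueError("size weighting requires n1 and n2")
        n1 = np.asarray(n1, float)
        n2 = np.asarray(n2, float)
        w1 = n1 / (n1 + n2)
        w2 = n2 / (n1 + n2)
    else:
        w1 = w2 = 0.5
    p_bar = w1 * p1 + w2 * p2
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    h_s = w1 * 2.0 * p1 * (1.0 - p1) + w2 * 2.0 * p2 * (1.0 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), np.nan)
    if fst.ndim == 0:
        return float(h_t), float(h_s), float(fst)
    return h_t, h_s, fst


# ---------------------------------------------------------------------------
# local regression
# ---------------------------------------------------------------------------

def loess_span(n_snps_on_chromosome: int, span_snps: int = 20) -> float:
    """Span fraction so each fit window holds *span_snps* markers: min(20/n, 1)."""
    if n_snps_on_chromosome < 1:
        raise ValueError("chromosome must carry at least one SNP")
    return min(span_snps / n_snps_on_chromosome, 1.0)


def lowess_smooth_chromosome(positions, fst_values, span: float) -> np.ndarray:
    """Locally weighted degree-1 smoothing of per-SNP values along a chromosome.

    At each marker the q = ceil(span*n) nearest markers by base-pair distance
    (ties broken by marker index) are fit with weighted least squares using
    tricube weights ``(1 - (d/d_max)^3)^3``, d_max being the largest distance
    in the neighborhood; the fitted line is evaluated at the marker's own
    position.  No robustness iterations.  If d_max = 0 the neighborhood mean
    is returned.
    """
    x = np.asarray(positions, float)
    y = np.asarray(fst_values, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points to smooth")
    if not 0 < span <= 1:
        raise ValueError(f"span {span} outside (0, 1]")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite (exclude undefined SNPs first)")

    q = min(n, max(1, math.ceil(span * n)))
    out = np.empty(n)
    idx_all = np.arange(n)
    for i in range(n):
        d = np.abs(x - x[i])
        # stable sort on distance; index order breaks ties deterministically
        nb = idx_all[np.argsort(d, kind="stable")[:q]]
        dn = d[nb]
        d_max = dn.max()
        if d_max == 0:
            out[i] = y[nb].mean()
            continue
        w = (1.0 - (dn / d_max) ** 3) ** 3
        sw = w.sum()
        if sw <= 0:  # pragma: no cover - q>=2 guarantees a positive weight at d=0
            out[i] = y[nb].mean()
            continue
        xc = x[nb] - x[i]
        yv = y[nb]
        sx = np.dot(w, xc)
        sxx = np.dot(w, xc * xc)
        sy = np.dot(w, yv)
        sxy = np.dot(w, xc * yv)
        denom = sw * sxx - sx * sx
        if denom <= 1e-12 * max(sw * sxx, sx * sx, 1e-300):
            out[i] = sy / sw
        else:
            # intercept of the weighted fit in coordinates centered at x[i]
            out[i] = (sxx * sy - sx * sxy) / denom
    return out


# ---------------------------------------------------------------------------
# control chart and signatures
# ---------------------------------------------------------------------------

def detect_outliers(
    snp_ids,
    smoothed_values,
    chromosome: int,
    sd_multiplier: float = 3.0,
    sd_estimator: str = "sample",
) -> OutlierCall:
    """Upper one-sided Shewhart rule on a chromosome's smoothed values.

    Flags markers whose smoothed value strictly exceeds
    ``mean + sd_multiplier * sigma`` where sigma is the sample (n-1) standard
    deviation, or the moving-range estimate ``mean(|x_i - x_{i-1}|)/1.128``
    when ``sd_estimator="moving_range"``.
    """
    values = np.asarray(smoothed_values, float)
    if len(values) < 2:
        raise ValueError("control chart needs at least 2 smoothed values per chromosome")
    mean = float(values.mean())
    if sd_estimator == "sample":
        sd = float(values.std(ddof=1))
    elif sd_estimator == "moving_range":
        sd = float(np.abs(np.diff(values)).mean() / 1.128)
    else:
        raise ValueError(f"unknown sd_estimator {sd_estimator!r}")
    limit = mean + sd_multiplier * sd
    flagged = [sid for sid, v in zip(snp_ids, values) if v > limit]
    return OutlierCall(
        chromosome=int(chromosome),
        mean_smoothed=mean,
        sd_smoothed=sd,
        upper_limit=limit,
        flagged_snp_ids=flagged,
    )


def cluster_signatures(outliers: pd.DataFrame, max_gap: int = 1_000_000) -> pd.DataFrame:
    """Merge consecutive outlier SNPs into selection signatures.

    *outliers* needs columns ``snp_id, chromosome, position, fst_smoothed``.
    Outliers on the same chromosome join one signature while every gap
    between consecutive members is at most *max_gap* bp.  The signature
    spans min to max member position; its peak is the member with the
    highest smoothed value (ties to the lowest position).
    """
    cols = ["signature_id", "chromosome", "start", "end", "n_outlier_snps",
            "peak_snp_id", "peak_value"]
    if len(outliers) == 0:
        return pd.DataFrame(columns=cols)
    df = outliers.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
    chrom = df["chromosome"].to_numpy()
    pos = df["position"].to_numpy()
    new_block = np.ones(len(df), bool)
    new_block[1:] = (chrom[1:] != chrom[:-1]) | ((pos[1:] - pos[:-1]) > max_gap)
    block = np.cumsum(new_block)
    rows = []
    for b, grp in df.groupby(block, sort=True):
        peak_idx = grp["fst_smoothed"].to_numpy().argmax()  # first max = lowest position
        rows.append(
            (
                f"SS{b:03d}",
                int(grp["chromosome"].iloc[0]),
                int(grp["position"].min()),
                int(grp["position"].max()),
                len(grp),
                grp["snp_id"].iloc[peak_idx],
                float(grp["fst_smoothed"].iloc[peak_idx]),
            )
        )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_scan(
    dataset: GenotypeDataset,
    assignments: pd.DataFrame,
    params: ScanParams | None = None,
) -> ScanResult:
    """Full differentiation scan: frequencies, F_ST, smoothing, outliers, signatures.

    Returns a :class:`ScanResult` whose ``scan_table`` is the Manhattan-ready
    per-SNP table (snp_id, chromosome, position, p1, p2, n1, n2, h_t, h_s,
    fst_raw, fst_smoothed, outlier) and whose ``signatures`` table groups the
    flagged SNPs.  Chromosomes with fewer than two informative SNPs are left
    unsmoothed and produce no outliers.
    """
    params = params or ScanParams()
    table = group_allele_frequencies(dataset, assignments)
    h_t, h_s, fst = nei_fst(
        table["p1"].to_numpy(), table["p2"].to_numpy(),
        table["n1"].to_numpy(), table["n2"].to_numpy(),
        weighting=params.weighting,
    )
    table["h_t"], table["h_s"], table["fst_raw"] = h_t, h_s, fst
    table["fst_smoothed"] = np.nan
    table["outlier"] = False
    usable = table["defined"].to_numpy() & np.isfinite(fst)

    outlier_calls: list[OutlierCall] = []
    for chrom in sorted(table["chromosome"].unique()):
        sel = np.flatnonzero((table["chromosome"] == chrom).to_numpy() & usable)
        if len(sel) < 2:
            continue
        span = loess_span(len(sel), params.span_snps)
        smoothed = lowess_smooth_chromosome(
            table["position"].to_numpy()[sel], fst[sel], span
        )
        table.loc[table.index[sel], "fst_smoothed"] = smoothed
        call = detect_outliers(
            table["snp_id"].to_numpy()[sel],
            smoothed,
            chrom,
            sd_multiplier=params.sd_multiplier,
            sd_estimator=params.sd_estimator,
        )
        outlier_calls.append(call)
        flagged = set(call.flagged_snp_ids)
        if flagged:
            hit = table.index[sel][[sid in flagged for sid in table["snp_id"].to_numpy()[sel]]]
            table.loc[hit, "outlier"] = True

    signatures = cluster_signatures(
        table.loc[table["outlier"], ["snp_id", "chromosome", "position", "fst_smoothed"]],
        max_gap=params.signature_max_gap_bp,
    )
    return ScanResult(scan_table=table, signatures=signatures, outlier_calls=outlier_calls)
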