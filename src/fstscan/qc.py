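"""Sample and marker quality control, plus IBS-based multidimensional scaling.

The filters mirror a standard SNP-chip QC pass on a two-group panel:
samples are dropped when their call rate falls below 0.95, then markers are
dropped when the call rate is not above 0.975, the minor allele frequency is
not above 0.02, or the Hardy-Weinberg exact-test p-value falls below 1e-5.
Threshold inequalities are read as retention conditions, so boundary cases
fail closed.  Marker statistics are computed on the post-sample-filter data
with all samples pooled.

The X chromosome (label 27) is treated as autosomal: the intended panels are
all-female, so diploid coding is correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io_formats import MISSING, GenotypeDataset


class QcError(ValueError):
    """Raised when quality control cannot produce a usable dataset."""


@dataclass(frozen=True)
class QcThresholds:
    """Retention thresholds for sample/marker QC.

    A sample is kept when its call rate is at least ``sample_call_rate_min``;
    a marker is kept when call rate > ``snp_call_rate_min``, MAF >
    ``maf_min`` and HWE exact p >= ``hwe_p_min``.
    """

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.975
    hwe_p_min: float = 1e-5
    maf_min: float = 0.02

    def __post_init__(self):
        for name in ("sample_call_rate_min", "snp_call_rate_min", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass
class QcReport:
    """Bookkeeping for one QC pass.

    ``markers_removed`` maps filter name -> list of snp_ids, attributing each
    removed marker to the first filter it failed (order: call_rate, maf, hwe).
    """

    samples_input: int = 0
    samples_removed: list = field(default_factory=list)  # (sample_id, reason)
    markers_input: int = 0
    markers_removed: dict = field(default_factory=dict)
    markers_retained: int = 0

    @property
    def samples_retained(self) -> int:
        return self.samples_input - len(self.samples_removed)

    def removal_counts(self) -> dict:
        return {k: len(v) for k, v in self.markers_removed.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_input", self.samples_input),
                ("samples_removed", len(self.samples_removed)),
                ("markers_input", self.markers_input)]
        rows += [(f"markers_removed_{k}", len(v)) for k, v in self.markers_removed.items()]
        rows.append(("markers_retained", self.markers_retained))
        return pd.DataFrame(rows, columns=["item", "count"])

    def summary_lines(self) -> list[str]:
        lines = [f"samples: {self.samples_input} in, {self.samples_retained} retained"]
        for sid, reason in self.samples_removed:
            lines.append(f"  removed sample {sid}: {reason}")
        lines.append(f"markers: {self.markers_input} in, {self.markers_retained} retained")
        for filt, ids in self.markers_removed.items():
            lines.append(f"  removed {len(ids)} markers by {filt}")
        return lines


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int, mid_p: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows the distribution

    ``P(n_Aa = h) ∝ n! / (n_AA! h! n_aa!) * 2**h``

    over all ``h`` with the parity of the minor-allele count.  The two-sided
    p-value sums the probabilities of every configuration no more likely than
    the observed one.  Monomorphic input returns 1.  With ``mid_p`` only half
    the observed configuration's probability is counted.

    Parameters are genotype counts (AA, Aa, aa homozygote/heterozygote
    classes); the test is symmetric in allele labels.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0

    rare = min(nA, na)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_AA_h = (nA - hets) // 2
    n_aa_h = (na - hets) // 2
    logw = (
        hets * np.log(2.0)
        - gammaln(n_AA_h + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(n_aa_h + 1.0)
    )
    logp = logw - logsumexp(logw)
    probs = np.exp(logp)
    p_obs = probs[hets == n_Aa][0]
    in_tail = probs <= p_obs * (1.0 + 1e-12)
    p = float(probs[in_tail].sum())
    if mid_p:
        p -= 0.5 * float(p_obs)
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Marker statistics (vectorized over the call matrix)
# ---------------------------------------------------------------------------

def _marker_stats(calls: np.ndarray):
    """Per-marker (call_rate, maf, genotype counts) on pooled samples."""
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / calls.shape[0] if calls.shape[0] else np.zeros(calls.shape[1])
    n_aa0 = ((calls == 0)).sum(axis=0)
    n_het = ((calls == 1)).sum(axis=0)
    n_bb = ((calls == 2)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = (n_het + 2 * n_bb) / (2 * n_obs)
    maf = np.where(n_obs > 0, np.minimum(freq_b, 1 - freq_b), 0.0)
    return call_rate, maf, n_aa0, n_het, n_bb, n_obs


def apply_qc(dataset: GenotypeDataset, thresholds: QcThresholds | None = None):
    """Filter a dataset, returning ``(clean_dataset, QcReport)``.

    Samples with call rate below ``sample_call_rate_min`` go first; marker
    statistics are then computed on the surviving samples and markers are
    removed by the first failing filter among call rate, MAF and HWE.
    Marker order is preserved.  Idempotent: a second pass removes nothing.
    """
    thresholds = thresholds or QcThresholds()
    report = QcReport(samples_input=dataset.n_samples, markers_input=dataset.n_markers)

    obs = dataset.calls != MISSING
    sample_cr = obs.mean(axis=1) if dataset.n_markers else np.ones(dataset.n_samples)
    keep_samples = sample_cr >= thresholds.sample_call_rate_min
    for idx in np.flatnonzero(~keep_samples):
        report.samples_removed.append(
            (dataset.samples["sample_id"].iloc[idx], f"call_rate={sample_cr[idx]:.4f}")
        )
    if not keep_samples.any():
        raise QcError("no samples survive the call-rate filter")

    calls = dataset.calls[keep_samples]
    call_rate, maf, n_aa0, n_het, n_bb, n_obs = _marker_stats(calls)

    fail_cr = call_rate <= thresholds.snp_call_rate_min
    fail_maf = (~fail_cr) & (maf <= thresholds.maf_min)
    remaining = np.flatnonzero(~(fail_cr | fail_maf))
    fail_hwe = np.zeros(dataset.n_markers, bool)
    for j in remaining:
        p = hwe_exact_test(int(n_aa0[j]), int(n_het[j]), int(n_bb[j]))
        if p < thresholds.hwe_p_min:
            fail_hwe[j] = True

    ids = dataset.markers["snp_id"]
    report.markers_removed = {
        "call_rate": ids[fail_cr].tolist(),
        "maf": ids[fail_maf].tolist(),
        "hwe": ids[fail_hwe].tolist(),
    }
    keep_markers = ~(fail_cr | fail_maf | fail_hwe)
    report.markers_retained = int(keep_markers.sum())
    if report.markers_retained == 0:
        raise QcError("no markers survive quality control")

    clean = dataset.subset(sample_mask=keep_samples, marker_mask=keep_markers)
    return clean, report


# ---------------------------------------------------------------------------
# IBS distance + classical MDS
# ---------------------------------------------------------------------------

def ibs_distance_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Pairwise ``1 - IBS/2`` distances over jointly non-missing markers.

    Per marker the allele-sharing score between genotypes g_i, g_j in
    {0,1,2} is ``2 - |g_i - g_j|``, so the distance contribution is
    ``|g_i - g_j| / 2``; averaging over jointly observed markers gives a
    distance in [0, 1].
    """
    calls = dataset.calls
    valid = (calls != MISSING).astype(np.float64)
    ind = [((calls == g) & (calls != MISSING)).astype(np.float64) for g in (0, 1, 2)]
    # sum over markers of |g_i - g_j| decomposed over genotype-pair classes
    d01 = ind[0] @ ind[1].T
    d02 = ind[0] @ ind[2].T
    d12 = ind[1] @ ind[2].T
    absdiff = d01 + d01.T + d12 + d12.T + 2.0 * (d02 + d02.T)
    joint = valid @ valid.T
    off_diag = ~np.eye(len(joint), dtype=bool)
    if (joint[off_diag] == 0).any():
        raise QcError("a sample pair shares zero non-missing markers")
    np.fill_diagonal(joint, np.maximum(joint.diagonal(), 1.0))
    return absdiff / (2.0 * joint)


def classical_mds(distance: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top-``k`` coordinates scaled by the square root of the eigenvalues
    (non-positive eigenvalues give zero coordinates).  The sign of each axis
    is fixed by making its first nonzero loading positive.
    """
    distance = np.asarray(distance, float)
    n = distance.shape[0]
    if distance.shape != (n, n):
        raise ValueError("distance matrix must be square")
    d2 = distance ** 2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * centerer @ d2 @ centerer
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    coords = np.zeros((n, k))
    # eigenvalues within numerical noise of zero carry no geometry
    tol = 1e-10 * max(float(eigval.max()), 1e-300)
    for axis, idx in enumerate(order):
        lam = eigval[idx]
        if lam <= tol:
            continue
        v = eigvec[:, idx]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        coords[:, axis] = np.sqrt(lam) * v
    return coords


def ibs_mds(dataset: GenotypeDataset, k: int = 2) -> pd.DataFrame:
    """Per-sample MDS coordinates of the IBS distance matrix.

    Returns a DataFrame with ``sample_id`` and columns ``mds1..mdsk``.
    """
    if dataset.n_samples < k + 1:
        raise QcError(f"need at least {k + 1} samples for {k}-dimensional MDS")
    coords = classical_mds(ibs_distance_matrix(dataset), k=k)
    out = pd.DataFrame({"sample_id": dataset.samples["sample_id"]})
    for axis in range(k):
        out[f"mds{axis + 1}"] = coords[:, axis]
    return out
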