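"""Readers and writers for the text formats the scan pipeline touches.

Genotypes travel as PED/MAP (the dialect of the QC tooling the study used),
gene annotation as GTF, and every result table as headered TSV.  All formats
are plain text.  The in-memory genotype container is :class:`GenotypeDataset`:
a sample table, a marker map sorted by chromosome then position, and a
``samples x markers`` call matrix counting copies of ``allele_b``
(0/1/2, :data:`MISSING` = -1 for no-calls).

Chromosome labels are normalized to integers 1-27; the ovine X chromosome is
encoded as 27 throughout, and written back out as ``"27"``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: call-matrix code for a missing genotype
MISSING = -1

#: integer label under which the X chromosome is stored
X_CHROMOSOME = 27

MARKER_COLUMNS = ["snp_id", "chromosome", "position", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "flock_id"]


class ParseError(ValueError):
    """Base class for file-format errors raised by this module."""


class MapParseError(ParseError):
    """Malformed MAP file."""


class PedParseError(ParseError):
    """Malformed PED file."""


class GtfParseError(ParseError):
    """Malformed GTF file."""


def normalize_chromosome(token) -> int:
    """Map a chromosome token to the internal integer label.

    Autosomes are ``1``-``26``; ``"X"`` (case-insensitive) and ``"27"`` both
    normalize to :data:`X_CHROMOSOME`.
    """
    if isinstance(token, str):
        tok = token.strip()
        if tok.upper() == "X":
            return X_CHROMOSOME
        if tok.upper().startswith("OAR"):
            tok = tok[3:]
        try:
            value = int(tok)
        except ValueError as exc:
            raise ParseError(f"unrecognized chromosome label {token!r}") from exc
    else:
        value = int(token)
    if not 1 <= value <= X_CHROMOSOME:
        raise ParseError(f"chromosome label {token!r} outside 1-{X_CHROMOSOME}")
    return value


def chromosome_label(chrom: int) -> str:
    """Render the internal chromosome integer for output (X prints as 27)."""
    return str(int(chrom))


@dataclass(frozen=True)
class MarkerRecord:
    """One SNP of the marker map (position is 1-based)."""

    snp_id: str
    chromosome: int
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class GeneRecord:
    """One gene feature from a GTF, 1-based inclusive coordinates."""

    gene_id: str
    gene_name: str
    chromosome: int
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenotypeDataset:
    """Samples x biallelic-SNP calls plus marker map and sample metadata.

    Attributes
    ----------
    samples:
        DataFrame with columns ``sample_id`` (unique) and ``flock_id``.
    markers:
        DataFrame with columns ``snp_id, chromosome, position, allele_a,
        allele_b``, sorted by (chromosome, position).
    calls:
        ``(n_samples, n_markers)`` int8 array; entries count copies of
        ``allele_b`` (0/1/2) or :data:`MISSING`.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample table missing column {col!r}")
        for col in MARKER_COLUMNS:
            if col not in self.markers.columns:
                raise ValueError(f"marker table missing column {col!r}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if self.markers["snp_id"].duplicated().any():
            dup = self.markers["snp_id"][self.markers["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.calls.size:
            vals = self.calls
            if vals.min() < MISSING or vals.max() > 2:
                raise ValueError("call matrix entries must be in {-1, 0, 1, 2}")
        chrom = self.markers["chromosome"].to_numpy()
        pos = self.markers["position"].to_numpy()
        if len(chrom) > 1:
            same = chrom[1:] == chrom[:-1]
            if (chrom[1:] < chrom[:-1]).any() or (same & (pos[1:] < pos[:-1])).any():
                raise ValueError("markers must be sorted by chromosome then position")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_mask=None, marker_mask=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the selected samples/markers."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        mmask = np.ones(self.n_markers, bool) if marker_mask is None else np.asarray(marker_mask)
        return GenotypeDataset(
            samples=self.samples.loc[smask].reset_index(drop=True),
            markers=self.markers.loc[mmask].reset_index(drop=True),
            calls=self.calls[np.ix_(smask, mmask)].copy(),
        )


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    records = []
    seen = set()
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) == 4:
                chrom_tok, snp_id, _cm, pos_tok = fields
            elif len(fields) == 3:
                chrom_tok, snp_id, pos_tok = fields
            else:
                raise MapParseError(
                    f"{map_path} line {lineno}: expected 3 or 4 columns, found {len(fields)}"
                )
            try:
                chrom = normalize_chromosome(chrom_tok)
            except ParseError as exc:
                raise MapParseError(f"{map_path} line {lineno}: {exc}") from exc
            try:
                pos = int(pos_tok)
            except ValueError as exc:
                raise MapParseError(
                    f"{map_path} line {lineno}: non-integer position {pos_tok!r}"
                ) from exc
            if pos < 1:
                raise MapParseError(f"{map_path} line {lineno}: position {pos} < 1")
            if snp_id in seen:
                raise MapParseError(f"{map_path} line {lineno}: duplicate snp_id {snp_id!r}")
            seen.add(snp_id)
            records.append((snp_id, chrom, pos))
    return pd.DataFrame(records, columns=["snp_id", "chromosome", "position"])


def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Parse a PED/MAP pair into a :class:`GenotypeDataset`.

    Allele coding is inferred per marker: ``allele_a`` is the first allele
    observed in file order, ``allele_b`` the second; the call matrix counts
    copies of ``allele_b``.  A ``0 0`` pair becomes :data:`MISSING`.  The
    PED family column is taken as the flock identifier.  Markers are sorted
    by (chromosome, position) on the way in.
    """
    marker_map = _read_map(map_path)
    m = len(marker_map)

    allele_a = np.full(m, "", dtype=object)
    allele_b = np.full(m, "", dtype=object)
    sample_ids: list[str] = []
    flock_ids: list[str] = []
    rows: list[np.ndarray] = []

    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise PedParseError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields for "
                    f"{m} MAP markers, found {len(fields)}"
                )
            sample_id = fields[1]
            if sample_id in sample_ids:
                raise PedParseError(f"{ped_path} line {lineno}: duplicate sample {sample_id!r}")
            alleles = np.array(fields[6:], dtype=object)
            a1, a2 = alleles[0::2], alleles[1::2]
            miss1, miss2 = a1 == "0", a2 == "0"
            half = miss1 ^ miss2
            if half.any():
                j = int(np.flatnonzero(half)[0])
                raise PedParseError(
                    f"{ped_path} line {lineno}: half-missing genotype at marker "
                    f"{marker_map['snp_id'].iloc[j]!r}"
                )
            missing = miss1 & miss2
            # establish allele coding in file order: a1 first, then a2
            for arr in (a1, a2):
                new_a = (~missing) & (allele_a == "")
                allele_a[new_a] = arr[new_a]
                new_b = (~missing) & (allele_b == "") & (arr != allele_a)
                allele_b[new_b] = arr[new_b]
            known = np.where(allele_b == "", allele_a, allele_b)
            bad = (~missing) & (
                ((a1 != allele_a) & (a1 != known)) | ((a2 != allele_a) & (a2 != known))
            )
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise PedParseError(
                    f"{ped_path} line {lineno}: more than two alleles at marker "
                    f"{marker_map['snp_id'].iloc[j]!r}"
                )
            counts = (a1 == allele_b).astype(np.int8) + (a2 == allele_b).astype(np.int8)
            counts[missing] = MISSING
            rows.append(counts)
            sample_ids.append(sample_id)
            flock_ids.append(fields[0])

    if not rows:
        raise PedParseError(f"{ped_path}: no samples")

    # markers never observed get placeholder alleles so the invariant holds
    allele_a[allele_a == ""] = "A"
    for j in np.flatnonzero(allele_b == ""):
        allele_b[j] = "B" if allele_a[j] != "B" else "0"

    markers = marker_map.assign(allele_a=allele_a, allele_b=allele_b)
    order = np.lexsort((markers["position"].to_numpy(), markers["chromosome"].to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)[MARKER_COLUMNS]
    calls = np.vstack(rows)[:, order]
    samples = pd.DataFrame({"sample_id": sample_ids, "flock_id": flock_ids})
    return GenotypeDataset(samples=samples, markers=markers, calls=calls)


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset as a PED/MAP pair (round-trips through read_ped_map)."""
    with open(map_path, "w") as fh:
        for rec in dataset.markers.itertuples(index=False):
            fh.write(f"{chromosome_label(rec.chromosome)}\t{rec.snp_id}\t0\t{rec.position}\n")

    a = dataset.markers["allele_a"].to_numpy(dtype=object)
    b = dataset.markers["allele_b"].to_numpy(dtype=object)
    m = len(a)
    # genotype strings per (code, marker): rows 0/1/2/missing
    choices = np.empty((4, m), dtype=object)
    for j in range(m):
        choices[0, j] = f"{a[j]} {a[j]}"
        choices[1, j] = f"{a[j]} {b[j]}"
        choices[2, j] = f"{b[j]} {b[j]}"
        choices[3, j] = "0 0"
    col_idx = np.arange(m)
    with open(ped_path, "w") as fh:
        for i, srec in enumerate(dataset.samples.itertuples(index=False)):
            codes = dataset.calls[i].astype(np.int64)
            codes[codes == MISSING] = 3
            geno = choices[codes, col_idx]
            fh.write(
                f"{srec.flock_id} {srec.sample_id} 0 0 0 -9 " + " ".join(geno) + "\n"
            )


# ---------------------------------------------------------------------------
# VCF (optional input-only path)
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, flock_of_sample: dict | None = None) -> GenotypeDataset:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeDataset`.

    Multiallelic records are skipped with a logged warning.  ``allele_b`` is
    the ALT allele.  Flock identifiers are looked up in *flock_of_sample*
    (default ``"UNKNOWN"`` for all samples).  Requires the optional cyvcf2
    dependency.
    """
    from cyvcf2 import VCF  # lazy: optional extra

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    records, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping multiallelic record %s:%s", variant.CHROM, variant.POS)
            continue
        chrom = normalize_chromosome(variant.CHROM)
        snp_id = variant.ID or f"{chrom}:{variant.POS}"
        records.append((snp_id, chrom, variant.POS, variant.REF, variant.ALT[0]))
        gt = np.asarray(variant.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        columns.append(col.astype(np.int8))
    markers = pd.DataFrame(records, columns=MARKER_COLUMNS)
    order = np.lexsort((markers["position"].to_numpy(), markers["chromosome"].to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    calls = np.column_stack(columns)[:, order] if columns else np.empty((len(sample_ids), 0), np.int8)
    flock_of_sample = flock_of_sample or {}
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "flock_id": [flock_of_sample.get(s, "UNKNOWN") for s in sample_ids],
        }
    )
    return GenotypeDataset(samples=samples, markers=markers, calls=calls)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(gtf_path) -> list[GeneRecord]:
    """Read ``gene`` features from a GTF file.

    Only rows whose feature column is ``gene`` are kept; ``gene_id`` is
    required, ``gene_name`` optional.  Coordinates stay 1-based inclusive.
    Comment lines (``#``) are ignored.
    """
    genes: list[GeneRecord] = []
    with open(gtf_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfParseError(
                    f"{gtf_path} line {lineno}: expected 9 tab-separated columns, "
                    f"found {len(cols)}"
                )
            if cols[2] != "gene":
                continue
            try:
                chrom = normalize_chromosome(cols[0])
                start, end = int(cols[3]), int(cols[4])
            except (ParseError, ValueError) as exc:
                raise GtfParseError(f"{gtf_path} line {lineno}: {exc}") from exc
            if start > end:
                raise GtfParseError(f"{gtf_path} line {lineno}: start {start} > end {end}")
            attrs = dict(_ATTR_RE.findall(cols[8]))
            if "gene_id" not in attrs:
                raise GtfParseError(f"{gtf_path} line {lineno}: missing gene_id attribute")
            genes.append(
                GeneRecord(
                    gene_id=attrs["gene_id"],
                    gene_name=attrs.get("gene_name", ""),
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=cols[6] if cols[6] in {"+", "-", "."} else ".",
                )
            )
    return genes


def genes_to_frame(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (g.gene_id, g.gene_name, g.chromosome, g.start, g.end, g.strand)
            for g in genes
        ],
        columns=["gene_id", "gene_name", "chromosome", "start", "end", "strand"],
    )


# ---------------------------------------------------------------------------
# CSV / TSV tables
# ---------------------------------------------------------------------------

def read_flock_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"flock_id", "lat", "lon"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: flock table missing columns {sorted(missing)}")
    df["flock_id"] = df["flock_id"].astype(str)
    return df


def read_station_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"station_id", "lat", "lon", "mean_tmax_c"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: station table missing columns {sorted(missing)}")
    df["station_id"] = df["station_id"].astype(str)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a result table as headered TSV (deterministic formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
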