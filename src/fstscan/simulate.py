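"""Synthetic two-population SNP panels with known differentiation structure.

The generator emulates the study design every downstream stage expects: two
groups of several hundred diploid ewes (defaults 395 "cold environment" and
430 "hot environment" animals across 46 flocks), tens of thousands of
biallelic SNPs on 27 chromosomes, low genome-wide background differentiation
with localized planted high-F_ST regions, and realistic missingness —
together with matching flock/station tables and a GTF gene annotation.

Allele frequencies follow the Balding-Nichols model: each SNP draws an
ancestral frequency p uniformly on [maf_floor, 1 - maf_floor] and each group
draws its frequency from

    Beta(p * (1-F)/F,  (1-p) * (1-F)/F)

with F the target F_ST (the background level, or the planted level inside a
planted region), which makes the expected realized Nei F_ST approximately F.
Genotypes are binomial(2, group frequency) per sample — within-group
Hardy-Weinberg equilibrium, so the HWE QC filter has calibrated behavior —
and calls are masked missing independently.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env_grouping import haversine_km
from .io_formats import MARKER_COLUMNS, MISSING, GenotypeDataset, chromosome_label


@dataclass(frozen=True)
class PlantedRegion:
    """A chromosome interval whose SNPs are simulated at elevated F_ST."""

    chromosome: int
    start: int
    end: int
    fst: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("planted region start must be < end")
        if not 0 < self.fst < 1:
            raise ValueError("planted fst must lie in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are sized to the study design this package targets: 395 + 430
    samples in 23 + 23 flocks, 27 chromosomes x 2,000 SNPs (~54k typed
    markers), background F_ST 0.01, 1% missing calls, ancestral minor-allele
    floor 0.05.
    """

    n_samples_per_group: tuple = (395, 430)
    n_chromosomes: int = 27
    snps_per_chromosome: int = 2_000
    chromosome_length: int = 100_000_000
    fst_background: float = 0.01
    planted_regions: tuple = ()
    missing_rate: float = 0.01
    maf_floor_ancestral: float = 0.05
    flocks_per_group: int = 23
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_regions", tuple(self.planted_regions))
        self.validate()

    def validate(self) -> None:
        if len(self.n_samples_per_group) != 2 or any(n < 1 for n in self.n_samples_per_group):
            raise ValueError("n_samples_per_group must be two positive counts")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one SNP")
        if self.snps_per_chromosome > self.chromosome_length:
            raise ValueError("more SNPs than base pairs on a chromosome")
        if not 0 < self.fst_background < 1:
            raise ValueError("fst_background must lie in (0, 1) for finite Beta parameters")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 < self.maf_floor_ancestral < 0.5:
            raise ValueError("maf_floor_ancestral must lie in (0, 0.5)")
        if self.flocks_per_group < 1:
            raise ValueError("flocks_per_group must be >= 1")
        by_chrom: dict[int, list[PlantedRegion]] = {}
        for region in self.planted_regions:
            if not 1 <= region.chromosome <= self.n_chromosomes:
                raise ValueError(f"planted region on unknown chromosome {region.chromosome}")
            if region.end > self.chromosome_length:
                raise ValueError("planted region extends beyond the chromosome")
            if region.fst <= self.fst_background:
                raise ValueError("fst_planted must exceed fst_background")
            by_chrom.setdefault(region.chromosome, []).append(region)
        for regions in by_chrom.values():
            regions = sorted(regions, key=lambda r: r.start)
            for a, b in zip(regions, regions[1:]):
                if b.start <= a.end:
                    raise ValueError("planted regions overlap")

    @property
    def n_samples_total(self) -> int:
        return int(sum(self.n_samples_per_group))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated panel.

    snp_table:
        per-SNP DataFrame: snp_id, chromosome, position, p_ancestral, p_ce,
        p_he, fst_target, planted (bool), region_index (-1 outside regions).
    sample_groups:
        DataFrame mapping sample_id to its true group (CE/HE).
    """

    snp_table: pd.DataFrame
    sample_groups: pd.DataFrame


def _strictly_increasing_positions(rng, n, length) -> np.ndarray:
    pos = np.sort(rng.integers(1, length + 1, size=n))
    # resolve duplicates by +1 bp nudging; maps must be strictly increasing
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def simulate_genotypes(config: SimulationConfig):
    """Draw a genotype panel; returns ``(GenotypeDataset, SimulationTruth)``.

    Identical configs (including seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_samples_per_group
    m_total = config.n_chromosomes * config.snps_per_chromosome

    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), config.snps_per_chromosome)
    positions = np.concatenate(
        [
            _strictly_increasing_positions(rng, config.snps_per_chromosome, config.chromosome_length)
            for _ in range(config.n_chromosomes)
        ]
    )
    snp_ids = np.array(
        [f"snp{c}_{p}" for c, p in zip(chroms, positions)], dtype=object
    )

    floor = config.maf_floor_ancestral
    p_anc = rng.uniform(floor, 1.0 - floor, size=m_total)

    fst_target = np.full(m_total, config.fst_background)
    region_index = np.full(m_total, -1)
    for r_idx, region in enumerate(config.planted_regions):
        inside = (
            (chroms == region.chromosome)
            & (positions >= region.start)
            & (positions <= region.end)
        )
        fst_target[inside] = region.fst
        region_index[inside] = r_idx
    planted = region_index >= 0

    shape = (1.0 - fst_target) / fst_target
    p_group = np.empty((2, m_total))
    for g in range(2):
        p_group[g] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)

    calls = np.empty((n1 + n2, m_total), dtype=np.int8)
    calls[:n1] = rng.binomial(2, p_group[0], size=(n1, m_total)).astype(np.int8)
    calls[n1:] = rng.binomial(2, p_group[1], size=(n2, m_total)).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    sample_ids = [f"S{i + 1:04d}" for i in range(n1 + n2)]
    flock_ids = (
        [f"FL{(i % config.flocks_per_group) + 1:03d}" for i in range(n1)]
        + [f"FL{config.flocks_per_group + (i % config.flocks_per_group) + 1:03d}" for i in range(n2)]
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "flock_id": flock_ids})
    markers = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chroms,
            "position": positions,
            "allele_a": "A",
            "allele_b": "B",
        }
    )[MARKER_COLUMNS]
    dataset = GenotypeDataset(samples=samples, markers=markers, calls=calls)

    truth = SimulationTruth(
        snp_table=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chromosome": chroms,
                "position": positions,
                "p_ancestral": p_anc,
                "p_ce": p_group[0],
                "p_he": p_group[1],
                "fst_target": fst_target,
                "planted": planted,
                "region_index": region_index,
            }
        ),
        sample_groups=pd.DataFrame(
            {"sample_id": sample_ids, "group": ["CE"] * n1 + ["HE"] * n2}
        ),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# environment tables
# ---------------------------------------------------------------------------

#: Sardinia-like bounding box used for fixture geography
_LAT_RANGE = (39.0, 41.0)
_LON_RANGE = (8.4, 9.9)


def simulate_environment_tables(
    n_flocks: int,
    n_stations: int,
    temp_range: tuple = (14.0, 28.0),
    seed: int = 0,
):
    """Random flock and weather-station tables on an island-sized bounding box.

    Stations get coordinates and a 20-year mean maximum temperature drawn
    uniformly from *temp_range*; each flock is placed near one station
    except the last, which is moved far north so it sits more than 50 km
    from every station (exercising the unassigned path).  Flocks carry an
    ``n_samples`` roster-size column.
    """
    if n_flocks < 1 or n_stations < 1:
        raise ValueError("need at least one flock and one station")
    lo, hi = temp_range
    if lo > hi:
        raise ValueError(f"empty temperature interval {temp_range}")
    rng = np.random.default_rng(seed)
    stations = pd.DataFrame(
        {
            "station_id": [f"ST{i + 1:02d}" for i in range(n_stations)],
            "lat": rng.uniform(*_LAT_RANGE, size=n_stations),
            "lon": rng.uniform(*_LON_RANGE, size=n_stations),
            "mean_tmax_c": rng.uniform(lo, hi, size=n_stations),
        }
    )
    anchor = rng.integers(0, n_stations, size=n_flocks)
    flocks = pd.DataFrame(
        {
            "flock_id": [f"FL{i + 1:03d}" for i in range(n_flocks)],
            "lat": stations["lat"].to_numpy()[anchor] + rng.uniform(-0.1, 0.1, size=n_flocks),
            "lon": stations["lon"].to_numpy()[anchor] + rng.uniform(-0.1, 0.1, size=n_flocks),
            "n_samples": rng.integers(5, 26, size=n_flocks),
        }
    )
    # last flock far outside the station network (> 50 km from every station)
    flocks.loc[len(flocks) - 1, ["lat", "lon"]] = (_LAT_RANGE[1] + 4.0, 9.0)
    return flocks, stations


# ---------------------------------------------------------------------------
# GTF fixture
# ---------------------------------------------------------------------------

def simulate_gtf(genes_per_chromosome: int, config: SimulationConfig, seed: int = 0) -> str:
    """Well-formed GTF text with gene features for the simulated genome.

    On chromosomes carrying planted regions the quota must cover one gene
    placed fully inside each region plus one gene more than 250 kb from any
    region; remaining genes are placed uniformly.  ``genes_per_chromosome=0``
    returns a header-only file.
    """
    header = "#!genome-build synthetic\n"
    if genes_per_chromosome == 0:
        return header
    rng = np.random.default_rng(seed)
    window = 250_000
    lines = [header.rstrip("\n")]
    counter = 0
    for chrom in range(1, config.n_chromosomes + 1):
        regions = [r for r in config.planted_regions if r.chromosome == chrom]
        needed = len(regions) + (1 if regions else 0)
        if genes_per_chromosome < needed:
            raise ValueError(
                f"chromosome {chrom}: quota {genes_per_chromosome} cannot cover "
                f"{len(regions)} planted regions plus one distant gene"
            )
        placements = []
        for region in regions:  # one gene fully inside each planted region
            span = region.end - region.start
            length = int(min(max(span // 10, 1_000), 40_000, span - 1))
            start = int(rng.integers(region.start, region.end - length + 1))
            placements.append((start, start + length))

        def far_from_regions(s, e):
            return all(s > r.end + window or e < r.start - window for r in regions)

        if regions:  # one gene > 250 kb from every planted region
            for _ in range(1000):
                length = int(rng.integers(5_000, 50_000))
                start = int(rng.integers(1, config.chromosome_length - length))
                if far_from_regions(start, start + length):
                    placements.append((start, start + length))
                    break
            else:  # pragma: no cover - generous genome leaves room
                raise ValueError(f"chromosome {chrom}: no room for a distant gene")
        while len(placements) < genes_per_chromosome:
            length = int(rng.integers(5_000, 50_000))
            start = int(rng.integers(1, config.chromosome_length - length))
            placements.append((start, start + length))
        for start, end in sorted(placements):
            counter += 1
            gid = f"SYNG{counter:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            lines.append(
                f"{chromosome_label(chrom)}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; gene_name "{gid}";'
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# coherent end-to-end study fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    """Everything one pipeline run consumes, generated from one seed."""

    dataset: GenotypeDataset
    truth: SimulationTruth
    flocks: pd.DataFrame
    stations: pd.DataFrame
    gtf_text: str


def simulate_study(
    config: SimulationConfig,
    n_stations: int = 39,
    temp_range: tuple = (14.0, 28.0),
    genes_per_chromosome: int = 8,
) -> StudyFixture:
    """Generate a coherent study: genotypes plus geography that reproduces them.

    Cold-group flocks are placed within a few km of cool stations (mean
    maximum temperature <= 20.5 degC) clustered in the north of the bounding
    box, hot-group flocks near warm stations (>= 21.5 degC) in the south, so
    nearest-station matching at 21 degC / 50 km recovers exactly the
    simulated group structure.  One extra sample-less flock sits far from
    every station.
    """
    lo, hi = temp_range
    if not (lo < 21.0 < hi):
        raise ValueError("temp_range must bracket the 21 degC breaking temperature")
    dataset, truth = simulate_genotypes(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    n_cold = n_stations // 2
    n_hot = n_stations - n_cold
    cold = pd.DataFrame(
        {
            "station_id": [f"ST{i + 1:02d}" for i in range(n_cold)],
            "lat": rng.uniform(40.4, 41.0, size=n_cold),
            "lon": rng.uniform(*_LON_RANGE, size=n_cold),
            "mean_tmax_c": rng.uniform(lo, 20.5, size=n_cold),
        }
    )
    hot = pd.DataFrame(
        {
            "station_id": [f"ST{i + 1 + n_cold:02d}" for i in range(n_hot)],
            "lat": rng.uniform(39.0, 39.6, size=n_hot),
            "lon": rng.uniform(*_LON_RANGE, size=n_hot),
            "mean_tmax_c": rng.uniform(21.5, hi, size=n_hot),
        }
    )
    stations = pd.concat([cold, hot], ignore_index=True)

    flock_rows = []
    group_of_sample = dict(
        zip(truth.sample_groups["sample_id"], truth.sample_groups["group"])
    )
    flock_group = (
        dataset.samples.assign(group=dataset.samples["sample_id"].map(group_of_sample))
        .groupby("flock_id")["group"]
        .first()  # flocks host a single group by construction
    )
    for fid in sorted(flock_group.index):
        pool = cold if flock_group[fid] == "CE" else hot
        j = int(rng.integers(0, len(pool)))
        flock_rows.append(
            (
                fid,
                float(pool["lat"].iloc[j]) + float(rng.uniform(-0.08, 0.08)),
                float(pool["lon"].iloc[j]) + float(rng.uniform(-0.08, 0.08)),
            )
        )
    flock_rows.append(("FL_FAR", 45.5, 9.0))  # unassignable, no samples
    flocks = pd.DataFrame(flock_rows, columns=["flock_id", "lat", "lon"])

    gtf_text = simulate_gtf(genes_per_chromosome, config, seed=config.seed + 1)
    return StudyFixture(
        dataset=dataset, truth=truth, flocks=flocks, stations=stations, gtf_text=gtf_text
    )
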