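"""Synthetic multi-patient WGS depth cohorts with known truth.

The generator emulates the features of tumor/normal whole-genome read-depth
data that the pipeline has to cope with: negative-binomial (overdispersed)
bin counts, focal alterations (<= 3 Mb) nested inside broad arm-level
events, reference N-gaps, sparse-mapping stretches, and per-patient
"fractured" tracks whose depth jitters in ~50 kb blocks (the excessive
read-depth-change artifact seen in a subset of TCGA GBM WGS samples).

Sparse-mapping stretches are modelled as severely *reduced* mapping rather
than exact zeros: bins with literally no normal reads have an undefined
ratio and are dropped before the transform, whereas the real artifact —
and the false deletions it causes — comes from the few reads that do map.

Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Interval
from .preprocess import BinnedCoverage

FOCAL_MAX_BP = 3_000_000
BROAD_MIN_CHROM_FRACTION = 0.25

# GBM cohort depth: mean genome-wide coverage 49.6x tumor / 43.7x normal;
# at ~100 bp reads this is the same number of read starts per 100-bp bin.
GBM_TUMOR_COVERAGE = 49.6
GBM_NORMAL_COVERAGE = 43.7


@dataclass(frozen=True)
class CNAEvent:
    """One planted copy-number event (coordinates 0-based half-open bp)."""

    chrom: str
    start: int
    end: int
    delta_log2: float
    kind: str  # "focal" | "broad"
    carriers: tuple[int, ...]


@dataclass(frozen=True)
class SparseRegion:
    """A stretch where reads map only sparsely (fractions of normal depth)."""

    chrom: str
    start: int
    end: int
    normal_fraction: float = 0.3
    tumor_fraction: float = 0.03


@dataclass(frozen=True)
class SimulationSpec:
    chromosomes: tuple[tuple[str, int], ...]
    n_patients: int
    bin_size: int = 100
    n_gaps: dict[str, list[Interval]] = field(default_factory=dict)
    sparse_regions: tuple[SparseRegion, ...] = ()
    tumor_coverage: float = GBM_TUMOR_COVERAGE      # mean reads per bin
    normal_coverage: float = GBM_NORMAL_COVERAGE
    events: tuple[CNAEvent, ...] = ()
    dispersion: float = 0.05        # NB: var = m + dispersion * m^2
    fractured_fraction: float = 0.0
    fracture_block_bp: int = 50_000
    fracture_sigma: float = 0.3     # log-normal sigma of the block factors
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for ev in self.events:
            if ev.chrom not in lengths:
                raise ValueError(f"event on unknown chromosome {ev.chrom}")
            if not 0 <= ev.start < ev.end <= lengths[ev.chrom]:
                raise ValueError(f"event {ev} outside its chromosome")
            size = ev.end - ev.start
            if ev.kind == "focal" and size > FOCAL_MAX_BP:
                raise ValueError(f"focal event longer than {FOCAL_MAX_BP} bp: {ev}")
            if ev.kind == "broad" and size <= BROAD_MIN_CHROM_FRACTION * lengths[ev.chrom]:
                raise ValueError(f"broad event spans <= 25% of its chromosome: {ev}")
            if ev.kind not in ("focal", "broad"):
                raise ValueError(f"unknown event kind {ev.kind!r}")
            if any(not 0 <= p < self.n_patients for p in ev.carriers):
                raise ValueError("carrier index outside cohort")
        for reg in self.sparse_regions:
            if reg.chrom not in lengths or not 0 <= reg.start < reg.end <= lengths[reg.chrom]:
                raise ValueError(f"sparse region {reg} outside its chromosome")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            chromosomes=self.chromosomes, bin_size=self.bin_size, n_gaps=self.n_gaps
        )


def _bin_range(layout: GenomeLayout, chrom: str, start: int, end: int) -> slice:
    ci = layout.chrom_index(chrom)
    off = int(layout.bin_offsets[ci])
    first = off + start // layout.bin_size
    last = off + (end - 1) // layout.bin_size
    return slice(first, last + 1)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    out = np.zeros(len(mean), dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        size = 1.0 / dispersion
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[GenomeLayout, list[tuple[BinnedCoverage, BinnedCoverage]], pd.DataFrame]:
    """Generate per-patient (tumor, normal) binned coverage plus the truth
    table of planted events.  Byte-identical for identical specs."""
    layout = spec.layout()
    nb = layout.total_bins
    keep_gaps = layout.keep_mask()  # N-gap bins zeroed in both samples

    base_normal = np.full(nb, spec.normal_coverage)
    base_tumor = np.full(nb, spec.tumor_coverage)
    sparse_n = np.ones(nb)
    sparse_t = np.ones(nb)
    for reg in spec.sparse_regions:
        sl = _bin_range(layout, reg.chrom, reg.start, reg.end)
        sparse_n[sl] = reg.normal_fraction
        sparse_t[sl] = reg.tumor_fraction

    root = np.random.SeedSequence(spec.seed)
    pick_rng = np.random.default_rng(root.spawn(1)[0])
    n_fractured = int(round(spec.fractured_fraction * spec.n_patients))
    fractured = set(
        pick_rng.choice(spec.n_patients, size=n_fractured, replace=False).tolist()
    )
    patient_seeds = root.spawn(spec.n_patients)

    pairs: list[tuple[BinnedCoverage, BinnedCoverage]] = []
    for p in range(spec.n_patients):
        rng = np.random.default_rng(patient_seeds[p])
        t_mean = base_tumor.copy()
        for ev in spec.events:
            if p in ev.carriers:
                sl = _bin_range(layout, ev.chrom, ev.start, ev.end)
                t_mean[sl] *= 2.0 ** ev.delta_log2  # overlapping events compound
        if p in fractured:
            block_bins = max(1, spec.fracture_block_bp // spec.bin_size)
            n_blocks = -(-nb // block_bins)
            factors = rng.lognormal(0.0, spec.fracture_sigma, size=n_blocks)
            t_mean *= np.repeat(factors, block_bins)[:nb]
        t_mean *= sparse_t
        n_mean = base_normal * sparse_n
        t_counts = _nb_draw(rng, t_mean, spec.dispersion).astype(float)
        n_counts = _nb_draw(rng, n_mean, spec.dispersion).astype(float)
        t_counts[~keep_gaps] = 0
        n_counts[~keep_gaps] = 0
        sid = f"patient{p:02d}"
        pairs.append(
            (
                BinnedCoverage(sid, "tumor", t_counts, layout),
                BinnedCoverage(sid, "normal", n_counts, layout),
            )
        )

    truth = pd.DataFrame(
        [
            {
                "chrom": ev.chrom,
                "start": ev.start,
                "end": ev.end,
                "delta_log2": ev.delta_log2,
                "kind": ev.kind,
                "carriers": ",".join(map(str, ev.carriers)),
            }
            for ev in spec.events
        ],
        columns=["chrom", "start", "end", "delta_log2", "kind", "carriers"],
    )
    return layout, pairs, truth


def spec_from_yaml(path: str) -> SimulationSpec:
    """Load a :class:`SimulationSpec` from a YAML file.

    Top-level keys mirror the dataclass fields; ``events`` and
    ``sparse_regions`` are lists of mappings with the obvious keys
    (``carriers`` as a list of patient indices).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["chromosomes"] = tuple((str(n), int(l)) for n, l in raw["chromosomes"])
    raw["events"] = tuple(
        CNAEvent(
            chrom=e["chrom"],
            start=int(e["start"]),
            end=int(e["end"]),
            delta_log2=float(e["delta_log2"]),
            kind=e["kind"],
            carriers=tuple(int(p) for p in e.get("carriers", ())),
        )
        for e in raw.get("events", ())
    )
    raw["sparse_regions"] = tuple(
        SparseRegion(
            chrom=s["chrom"],
            start=int(s["start"]),
            end=int(s["end"]),
            normal_fraction=float(s.get("normal_fraction", 0.3)),
            tumor_fraction=float(s.get("tumor_fraction", 0.03)),
        )
        for s in raw.get("sparse_regions", ())
    )
    if "n_gaps" in raw:
        raw["n_gaps"] = {
            chrom: [tuple(iv) for iv in ivs] for chrom, ivs in raw["n_gaps"].items()
        }
    return SimulationSpec(**raw)


def spec_gbm_defaults(
    n_patients: int = 20,
    n_carriers: int = 6,
    chrom_mb: float = 30,
    seed: int = 0,
) -> SimulationSpec:
    """A small-genome cohort spec mirroring the GBM study conditions.

    Three ``chrom_mb``-Mb chromosomes at 100-bp bins; tumor/normal coverage
    at the GBM cohort means (ratio 49.6/43.7); a focal amplification
    (delta log2 = 1.0, 1 Mb or 10% of the chromosome, whichever is smaller)
    nested inside a broad gain (delta log2 = 0.3, 40% of the chromosome) on
    chr1, carried by the first ``n_carriers`` patients; a small N-gap on
    each chromosome.
    """
    L = int(chrom_mb * 1_000_000)
    chroms = tuple((f"chr{i}", L) for i in (1, 2, 3))
    carriers = tuple(range(n_carriers))
    focal_half = min(500_000, L // 20)
    center = int(0.35 * L)
    return SimulationSpec(
        chromosomes=chroms,
        n_patients=n_patients,
        n_gaps={name: [(int(0.73 * L), int(0.75 * L))] for name, _ in chroms},
        events=(
            CNAEvent("chr1", int(0.2 * L), int(0.6 * L), 0.3, "broad", carriers),
            CNAEvent("chr1", center - focal_half, center + focal_half, 1.0, "focal", carriers),
        ),
        seed=seed,
    )
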