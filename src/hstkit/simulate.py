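"""Founder-haplotype cohort simulator.

Emulates the inheritance model the gamma-method estimator assumes: a
single founder haplotype is transmitted to ``n_carriers`` present-day
haplotypes over ``tau`` generations, and on each side of the focal locus
every carrier retains the founder sequence up to a recombination
breakpoint whose genetic distance from the locus is Exponential(tau)
Morgans.  Outside the breakpoints — and on all control chromosomes —
alleles are drawn independently from per-marker background frequencies,
so background linkage disequilibrium is deliberately absent and chance
sharing is minimal.

Each carrier haplotype is paired with a background haplotype into a
diploid sample (on a random strand, as phasing would deliver it), and
optional switch errors are planted by swapping the two strand suffixes
from a random marker on.  Everything is deterministic given the seed,
and the generator emits a truth file with the founder haplotype and
every carrier's exact breakpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneticMap, Haplotype, HaplotypeMatrix, VariantInfo

__all__ = ["SimulationParams", "SimulationTruth", "Simulation", "simulate_cohort"]

#: non-complementary ref/alt pairs, so cross-array harmonization never
#: drops simulated markers as strand-ambiguous
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"))


@dataclass
class SimulationParams:
    n_carriers: int = 100
    n_controls: int = 0
    n_markers: int = 1000
    spacing_bp: int = 5000
    positions: np.ndarray | None = None  # overrides n_markers/spacing
    freq_range: tuple[float, float] = (0.05, 0.95)
    tau: float = 30.0
    cM_per_Mb: float = 1.0
    switch_error_rate: float = 0.0
    contig: str = "1"
    first_pos: int = 1_000_000
    focal_pos: int | None = None  # default: middle marker
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carriers < 0 or self.n_controls < 0 or self.n_markers < 0:
            raise ValueError("counts must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.switch_error_rate <= 1:
            raise ValueError("switch_error_rate must be in [0, 1]")
        if self.cM_per_Mb <= 0:
            raise ValueError("cM_per_Mb must be positive")


@dataclass
class SimulationTruth:
    founder: np.ndarray  # founder alleles, one per marker
    left_break_bp: np.ndarray  # per carrier, continuous bp coordinate
    right_break_bp: np.ndarray
    left_len_morgans: np.ndarray  # exact exponential draws per side
    right_len_morgans: np.ndarray
    switch_errors: list[tuple[str, int]]  # (sample id, marker position)
    tau: float
    seed: int
    focal_pos: int = 0


@dataclass
class Simulation:
    params: SimulationParams
    matrix: HaplotypeMatrix
    genetic_map: GeneticMap
    truth: SimulationTruth
    carrier_rows: np.ndarray  # matrix row index of each carrier haplotype
    focal_idx: int

    def write(self, out_dir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        """Write VCF.gz, PLINK map, truth TSV and truth JSON."""
        from .io import write_genetic_map, write_phased_vcf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / f"{prefix}.vcf.gz",
            "map": out / f"{prefix}.map",
            "truth_tsv": out / f"{prefix}.truth.tsv",
            "truth_json": out / f"{prefix}.truth.json",
        }
        write_phased_vcf(self.matrix, paths["vcf"])
        write_genetic_map(self.genetic_map, paths["map"])
        t = self.truth
        pd.DataFrame(
            {
                "sample": [f"carrier{i}" for i in range(len(t.left_break_bp))],
                "row": self.carrier_rows,
                "left_break_bp": t.left_break_bp,
                "right_break_bp": t.right_break_bp,
                "left_len_morgans": t.left_len_morgans,
                "right_len_morgans": t.right_len_morgans,
            }
        ).to_csv(paths["truth_tsv"], sep="\t", index=False)
        paths["truth_json"].write_text(
            json.dumps(
                {
                    "tau": t.tau,
                    "seed": t.seed,
                    "focal_pos": t.focal_pos,
                    "founder": t.founder.tolist(),
                    "switch_errors": t.switch_errors,
                },
                indent=1,
            )
        )
        return paths

    @property
    def founder_haplotype(self) -> Haplotype:
        return Haplotype(
            variants=list(self.matrix.variants),
            alleles=self.truth.founder,
            marker_indices=np.arange(self.matrix.n_markers),
        )


def simulate_cohort(params: SimulationParams) -> Simulation:
    """Generate a phased cohort with a planted founder haplotype."""
    p = params
    rng = np.random.default_rng(p.seed)
    if p.positions is not None:
        positions = np.asarray(p.positions, dtype=np.int64)
        if np.any(np.diff(positions) <= 0):
            raise ValueError("explicit positions must be strictly increasing")
    else:
        positions = p.first_pos + p.spacing_bp * np.arange(p.n_markers, dtype=np.int64)
    nm = positions.size
    if nm == 0:
        raise ValueError("cannot simulate a cohort with zero markers")
    if p.n_carriers + p.n_controls == 0:
        raise ValueError("cannot simulate a cohort with zero samples")

    ref_alt = rng.integers(0, len(_ALLELE_PAIRS), size=nm)
    variants = [
        VariantInfo(p.contig, int(pos), f"m{j}", *_ALLELE_PAIRS[ref_alt[j]])
        for j, pos in enumerate(positions)
    ]
    freqs = rng.uniform(*p.freq_range, size=nm)
    founder = (rng.random(nm) < freqs).astype(np.uint8)

    if p.focal_pos is None:
        focal_idx = nm // 2
    else:
        focal_idx = int(np.flatnonzero(positions == p.focal_pos)[0])
    focal_pos = int(positions[focal_idx])

    bp_per_morgan = 1e8 / p.cM_per_Mb  # uniform map: 1 M = 100 cM

    def background(n_rows: int) -> np.ndarray:
        return (rng.random((n_rows, nm)) < freqs[None, :]).astype(np.uint8)

    # carriers: founder between per-side exponential breakpoints
    left_len = rng.exponential(1.0 / p.tau, size=p.n_carriers)
    right_len = rng.exponential(1.0 / p.tau, size=p.n_carriers)
    left_break = focal_pos - left_len * bp_per_morgan
    right_break = focal_pos + right_len * bp_per_morgan
    carriers = background(p.n_carriers)
    for i in range(p.n_carriers):
        inside = (positions > left_break[i]) & (positions < right_break[i])
        carriers[i, inside] = founder[inside]

    carrier_strand = rng.integers(0, 2, size=p.n_carriers)
    partners = background(p.n_carriers)
    controls = background(2 * p.n_controls)

    n_samples = p.n_carriers + p.n_controls
    data = np.empty((2 * n_samples, nm), dtype=np.uint8)
    carrier_rows = np.empty(p.n_carriers, dtype=np.int64)
    sample_ids = []
    for i in range(p.n_carriers):
        s = carrier_strand[i]
        data[2 * i + s] = carriers[i]
        data[2 * i + 1 - s] = partners[i]
        carrier_rows[i] = 2 * i + s
        sample_ids.append(f"carrier{i}")
    for i in range(p.n_controls):
        r = 2 * (p.n_carriers + i)
        data[r] = controls[2 * i]
        data[r + 1] = controls[2 * i + 1]
        sample_ids.append(f"control{i}")

    switch_errors: list[tuple[str, int]] = []
    if p.switch_error_rate > 0:
        for s in range(n_samples):
            if rng.random() < p.switch_error_rate:
                k = int(rng.integers(1, nm))  # swap suffixes from marker k on
                r = 2 * s
                tmp = data[r, k:].copy()
                data[r, k:] = data[r + 1, k:]
                data[r + 1, k:] = tmp
                switch_errors.append((sample_ids[s], int(positions[k])))

    matrix = HaplotypeMatrix(
        variants=variants, data=data, sample_ids=sample_ids, ploidy=2
    )
    gmap = GeneticMap.uniform(
        p.contig,
        int(positions[0] - p.spacing_bp),
        int(positions[-1] + p.spacing_bp),
        p.cM_per_Mb,
    )
    truth = SimulationTruth(
        founder=founder,
        left_break_bp=left_break,
        right_break_bp=right_break,
        left_len_morgans=left_len,
        right_len_morgans=right_len,
        switch_errors=switch_errors,
        tau=p.tau,
        seed=p.seed,
        focal_pos=focal_pos,
    )
    return Simulation(
        params=p,
        matrix=matrix,
        genetic_map=gmap,
        truth=truth,
        carrier_rows=carrier_rows,
        focal_idx=focal_idx,
    )
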