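"""Synthetic case-control cohorts with simulated STR-PCR / TP-PCR readouts.

The generator draws a two-locus genotype for every subject (CTG18.1
expansion collapsed to N/X plus the rs613872 T/G SNP, linked at a target
D') and then emulates what the lab observes:

* **STR-PCR**: one fluorescent peak per amplifiable allele at the nominal
  product size plus capillary sizing error, and a gel lane in which
  products closer than the gel's resolution merge into one band.  Expanded
  alleles (> 40 triplets) fail to amplify (allelic dropout) - by default
  deterministically, optionally via a logistic dropout curve.
* **TP-PCR**: the 3 bp ladder of both alleles superimposed.  Rung k is
  covered by every allele with at least k triplets, and rung intensity
  decays geometrically along the tract, so long expansions fade into the
  noise floor and their repeat count is right-censored.

Sizing error is dominated by run-to-run calibration, so a single per-trace
shift (``sizing_noise_sd``) is shared by all peaks of an injection, with a
small independent per-peak jitter on top; this keeps the 3 bp rung spacing
intact, as it is in real capillary data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .peaks import Assay, GelLane, GenotypeClass, Peak, PeakTable
from .reference import EXPANSION_COUNTS, SNP_COUNTS
from .sizing import SizingModel, str_product_size

__all__ = [
    "SimConfig",
    "Subject",
    "AssayData",
    "haplotype_frequencies",
    "simulate_cohort",
    "simulate_str_assay",
    "simulate_tp_assay",
    "simulate_assays",
    "reference_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Cohort and instrument model parameters.

    Genotype frequencies are parameterized per status (case-control
    sampling); within each status, haplotypes pair at random (HWE).  The
    defaults reproduce the Greek FECD study conditions: 36 cases / 58
    controls, expanded-allele frequency 32% vs 3%, risk-G frequency 40% vs
    17%, D' = 0.76 between the two risk alleles.
    """

    n_cases: int = 36
    n_controls: int = 58
    x_freq_cases: float = 0.32
    x_freq_controls: float = 0.03
    g_freq_cases: float = 0.40
    g_freq_controls: float = 0.17
    d_prime: float = 0.76
    normal_repeat_range: tuple[int, int] = (10, 35)
    expanded_repeat_range: tuple[int, int] = (41, 150)
    # instrument model
    sizing_noise_sd: float = 0.7  # per-trace calibration shift, bp
    local_jitter_sd: float = 0.12  # per-peak sizing jitter, bp
    str_amplitude: float = 4000.0  # fluorescence units per allele
    tp_amplitude: float = 1000.0  # first-rung units per allele
    height_sigma: float = 0.25  # log-normal sigma on peak heights
    intensity_decay: float = 0.97  # per-triplet TP rung decay
    noise_floor: float = 20.0  # detection floor, fluorescence units
    dropout_threshold: int = 40  # STR dropout above this repeat count
    dropout_logistic_scale: float | None = None  # soft dropout width (repeats)
    gel_resolution_bp: float = 6.0  # 4% high-resolution agarose
    # demographics (matched case/control design)
    female_fraction: float = 0.57
    age_mean: float = 73.0
    age_sd: float = 8.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for f in (self.x_freq_cases, self.x_freq_controls,
                  self.g_freq_cases, self.g_freq_controls):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele frequencies must lie in [0, 1]")
        if not 0.0 < self.intensity_decay <= 1.0:
            raise ValueError("intensity decay must lie in (0, 1]")
        if self.sizing_noise_sd < 0 or self.local_jitter_sd < 0:
            raise ValueError("sizing noise must be non-negative")

    def noise_free(self) -> "SimConfig":
        """Copy of this config with all measurement noise switched off."""
        return dataclasses.replace(
            self, sizing_noise_sd=0.0, local_jitter_sd=0.0, height_sigma=0.0
        )


@dataclass
class Subject:
    subject_id: str
    status: str  # "case" | "control"
    sex: str  # "F" | "M"
    age: int
    expansion_repeats: tuple[int, int]  # true per-allele CTG counts
    snp_genotype: str  # "TT" | "GT" | "GG"

    @property
    def x_dose(self) -> int:
        return sum(n > 40 for n in self.expansion_repeats)

    @property
    def g_dose(self) -> int:
        return self.snp_genotype.count("G")

    @property
    def true_class(self) -> GenotypeClass:
        return (GenotypeClass.NN, GenotypeClass.NX, GenotypeClass.XX)[self.x_dose]


@dataclass
class AssayData:
    """Everything the lab would see for one sample."""

    subject_id: str
    str_table: PeakTable
    gel_lane: GelLane
    tp_table: PeakTable


def haplotype_frequencies(p_a: float, p_b: float, d_prime: float) -> np.ndarray:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) with normalized LD
    ``d_prime`` between the risk alleles A and B.

    D' scales the raw disequilibrium D by its frequency-determined maximum,
    so any value in [-1, 1] is feasible; anything outside is rejected.
    """
    if not -1.0 <= d_prime <= 1.0:
        raise ValueError(
            f"target D' = {d_prime} infeasible: D' must lie within [-1, 1]"
        )
    if d_prime >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d = d_prime * d_max
    freqs = np.array([
        p_a * p_b + d,
        p_a * (1 - p_b) - d,
        (1 - p_a) * p_b - d,
        (1 - p_a) * (1 - p_b) + d,
    ])
    freqs[np.abs(freqs) < 1e-15] = 0.0
    return freqs


def _draw_repeat(expanded: bool, config: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = config.expanded_repeat_range if expanded else config.normal_repeat_range
    return int(rng.integers(lo, hi + 1))


def simulate_cohort(config: SimConfig, seed: int | None = None) -> list[Subject]:
    """Draw a case-control cohort with the configured two-locus structure.

    Reproducible: the same config + seed yields the identical cohort.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subjects: list[Subject] = []
    groups = (
        ("case", config.n_cases, config.x_freq_cases, config.g_freq_cases),
        ("control", config.n_controls, config.x_freq_controls, config.g_freq_controls),
    )
    for status, n, p_x, p_g in groups:
        freqs = haplotype_frequencies(p_x, p_g, config.d_prime)
        prefix = "F" if status == "case" else "C"
        for i in range(n):
            haps = rng.choice(4, size=2, p=freqs)  # 0=XG 1=Xt 2=xG 3=xt
            x_alleles = [h < 2 for h in haps]
            g_count = int(sum(h in (0, 2) for h in haps))
            repeats = tuple(_draw_repeat(x, config, rng) for x in x_alleles)
            sex = "F" if rng.random() < config.female_fraction else "M"
            age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 40, 95))
            subjects.append(
                Subject(
                    subject_id=f"{prefix}{i + 1:03d}",
                    status=status,
                    sex=sex,
                    age=age,
                    expansion_repeats=tuple(sorted(repeats)),
                    snp_genotype=("TT", "GT", "GG")[g_count],
                )
            )
    return subjects


def _allele_dropped(n: int, config: SimConfig, rng: np.random.Generator) -> bool:
    if config.dropout_logistic_scale is None:
        return n > config.dropout_threshold
    p = 1.0 / (1.0 + np.exp(-(n - config.dropout_threshold) / config.dropout_logistic_scale))
    return bool(rng.random() < p)


def _height_noise(config: SimConfig, rng: np.random.Generator) -> float:
    if config.height_sigma == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, config.height_sigma)))


def simulate_str_assay(
    subject: Subject,
    config: SimConfig,
    rng: np.random.Generator,
    model: SizingModel = SizingModel(),
) -> tuple[PeakTable, GelLane]:
    """STR-PCR readout: fragment-analysis peaks plus the gel lane.

    Identical alleles co-migrate as one product of doubled amplitude;
    expanded alleles drop out per the dropout rule; gel bands are the
    products merged at the gel's resolution with coarse (integer bp) sizes.
    """
    shift = rng.normal(0.0, config.sizing_noise_sd) if config.sizing_noise_sd else 0.0
    products: dict[int, int] = {}
    for n in subject.expansion_repeats:
        if not _allele_dropped(n, config, rng):
            products[n] = products.get(n, 0) + 1
    peaks = []
    for n, mult in sorted(products.items()):
        size = str_product_size(n, model) + shift + (
            rng.normal(0.0, config.local_jitter_sd) if config.local_jitter_sd else 0.0
        )
        height = mult * config.str_amplitude * _height_noise(config, rng)
        peaks.append(Peak(size_bp=size, height=height))
    table = PeakTable(sample_id=subject.subject_id, assay=Assay.STR, peaks=peaks)

    bands: list[tuple[float, float]] = []
    for p in table.peaks:
        if bands and p.size_bp - bands[-1][0] < config.gel_resolution_bp:
            prev_size, prev_int = bands.pop()
            w = prev_int + p.height
            bands.append(((prev_size * prev_int + p.size_bp * p.height) / w, w))
        else:
            bands.append((p.size_bp, p.height))
    lane = GelLane(
        sample_id=subject.subject_id,
        bands=[(float(round(s)), h) for s, h in bands],
    )
    return table, lane


def simulate_tp_assay(
    subject: Subject,
    config: SimConfig,
    rng: np.random.Generator,
    model: SizingModel = SizingModel(),
) -> PeakTable:
    """TP-PCR readout: the superimposed 3 bp ladders of both alleles.

    Rung k (k = 5..n) is covered by every allele of at least k triplets and
    its intensity decays geometrically with k, so the terminal rungs of a
    long expansion sink below the detection floor: the simulator simply
    does not emit them, which right-censors the downstream repeat estimate.
    """
    shift = rng.normal(0.0, config.sizing_noise_sd) if config.sizing_noise_sd else 0.0
    n1, n2 = subject.expansion_repeats
    anchor = model.tp_anchor_triplets
    peaks = []
    for k in range(anchor, max(n1, n2) + 1):
        coverage = (n1 >= k) + (n2 >= k)
        base = config.tp_amplitude * coverage * config.intensity_decay ** (k - anchor)
        height = base * _height_noise(config, rng)
        if height < config.noise_floor:
            continue
        size = (
            model.tp_offset_bp + model.triplet_bp * k + shift
            + (rng.normal(0.0, config.local_jitter_sd) if config.local_jitter_sd else 0.0)
        )
        peaks.append(Peak(size_bp=size, height=height))
    return PeakTable(sample_id=subject.subject_id, assay=Assay.TP, peaks=peaks)


def simulate_assays(
    subjects: list[Subject], config: SimConfig, seed: int | None = None
) -> list[AssayData]:
    """Simulate both assays for a whole cohort (one reproducible stream)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for s in subjects:
        str_table, lane = simulate_str_assay(s, config, rng)
        tp_table = simulate_tp_assay(s, config, rng)
        out.append(AssayData(s.subject_id, str_table, lane, tp_table))
    return out


def reference_cohort(seed: int = 0, config: SimConfig = SimConfig()) -> list[Subject]:
    """A cohort with exactly the published study's genotype composition.

    Expansion classes per status (cases 16 N/N, 17 N/X, 3 X/X; controls
    55/3/0) and SNP genotypes (cases 14/15/7 T/T, G/T, G/G; controls
    38/20/0) are laid down with their exact marginal counts and paired at
    random; individual repeat lengths are drawn from the configured
    ranges.  Useful for exercising the diagnostic workflows on the study's
    actual class mix.
    """
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    spec = {
        "case": (EXPANSION_COUNTS.cases, SNP_COUNTS.cases),
        "control": (EXPANSION_COUNTS.controls, SNP_COUNTS.controls),
    }
    for status, (exp_counts, snp_counts) in spec.items():
        x_doses = np.repeat([0, 1, 2], exp_counts)
        g_doses = rng.permutation(np.repeat([0, 1, 2], snp_counts))
        prefix = "F" if status == "case" else "C"
        for i, (xd, gd) in enumerate(zip(x_doses, g_doses)):
            repeats = tuple(
                sorted(_draw_repeat(j < xd, config, rng) for j in range(2))
            )
            sex = "F" if rng.random() < config.female_fraction else "M"
            age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 40, 95))
            subjects.append(
                Subject(
                    subject_id=f"{prefix}{i + 1:03d}",
                    status=status,
                    sex=sex,
                    age=age,
                    expansion_repeats=repeats,
                    snp_genotype=("TT", "GT", "GG")[gd],
                )
            )
    return subjects
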