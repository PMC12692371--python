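"""The two diagnostic decision algorithms and their head-to-head comparison.

*Established* workflow: every sample gets the gel, STR fragment analysis and
TP-PCR fragment analysis, and the genotype is adjudicated from the combined
evidence.

*Proposed cost-effective* workflow: every sample gets only the gel first.
Two clearly separated bands, both within the normal size range
(<= 235 bp), settle the sample as N/N with no fragment analysis at all.
Anything else — one band (homozygote or expanded-allele dropout), no band
(biallelic dropout), a band beyond the normal range, or two bands too close
to trust — escalates straight to TP-PCR fragment analysis; the STR products
are never re-run on the capillary.  Ambiguity always escalates rather than
classifies, so the proposed path can cost more on awkward samples but never
returns a different genotype class than the established one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .peaks import (
    AlleleCall,
    CallerParams,
    CallMethod,
    DiscordanceError,
    ExpansionGenotype,
    GenotypeClass,
    call_str_alleles,
    genotype_from_assays,
    segment_tp_ladder,
)
from .simulate import AssayData
from .sizing import ClassificationRule, SizingModel, str_size_to_repeats

__all__ = [
    "CostConfig",
    "WorkflowResult",
    "WorkflowComparison",
    "run_established",
    "run_proposed",
    "compare_workflows",
]


@dataclass(frozen=True)
class CostConfig:
    """Per-assay costs in abstract units (no currency is implied)."""

    gel: float = 1.0
    str_fragment: float = 3.0
    tp_fragment: float = 3.0
    sequencing: float = 5.0

    def __post_init__(self) -> None:
        if min(self.gel, self.str_fragment, self.tp_fragment, self.sequencing) < 0:
            raise ValueError("assay costs must be non-negative")

    def of(self, assay: str) -> float:
        return getattr(self, assay)


@dataclass
class WorkflowResult:
    sample_id: str
    genotype: ExpansionGenotype | None
    assays_performed: list[str]
    cost_units: float
    status: str = "ok"  # ok | incomplete | discordant
    escalated: bool = False
    notes: list[str] = field(default_factory=list)


def _finish(
    sample_id: str,
    genotype: ExpansionGenotype | None,
    assays: list[str],
    costs: CostConfig,
    status: str = "ok",
    escalated: bool = False,
    notes: list[str] | None = None,
) -> WorkflowResult:
    if genotype is not None and genotype.needs_sequencing and "sequencing" not in assays:
        assays = assays + ["sequencing"]
    return WorkflowResult(
        sample_id=sample_id,
        genotype=genotype,
        assays_performed=assays,
        cost_units=sum(costs.of(a) for a in assays),
        status=status,
        escalated=escalated,
        notes=notes or [],
    )


def run_established(
    data: AssayData,
    model: SizingModel = SizingModel(),
    rule: ClassificationRule = ClassificationRule(),
    params: CallerParams = CallerParams(),
    costs: CostConfig = CostConfig(),
) -> WorkflowResult:
    """Full protocol: gel + STR fragment analysis + TP fragment analysis."""
    assays = ["gel", "str_fragment", "tp_fragment"]
    str_calls = call_str_alleles(data.str_table, model, params)
    tp_clusters = segment_tp_ladder(data.tp_table, model, params)
    if not str_calls and not tp_clusters:
        return _finish(
            data.subject_id, None, assays, costs,
            status="incomplete", notes=["no signal in either assay"],
        )
    try:
        genotype = genotype_from_assays(str_calls, tp_clusters, rule, params)
    except DiscordanceError as exc:
        return _finish(
            data.subject_id, None, assays, costs,
            status="discordant", notes=[str(exc)],
        )
    return _finish(data.subject_id, genotype, assays, costs)


def _gel_calls(
    bands: list[tuple[float, float]], model: SizingModel
) -> list[AlleleCall]:
    calls = []
    for size, _intensity in bands:
        est = str_size_to_repeats(size, model)
        calls.append(
            AlleleCall(
                repeat_count=est.repeats,
                size_bp=size,
                method=CallMethod.GEL,
                residual_bp=est.residual_bp,
                sizing_warning=est.sizing_warning,
            )
        )
    return calls


def run_proposed(
    data: AssayData,
    model: SizingModel = SizingModel(),
    rule: ClassificationRule = ClassificationRule(),
    params: CallerParams = CallerParams(),
    costs: CostConfig = CostConfig(),
    gel_ambiguity_bp: float = 6.0,
) -> WorkflowResult:
    """Gel-first protocol with escalation to TP-PCR fragment analysis.

    ``gel_ambiguity_bp``: two bands separated by less than this are not
    trusted as two distinct products (the gel may be showing one smeared
    band) and the sample escalates.
    """
    bands = sorted(data.gel_lane.bands)
    calls = _gel_calls(bands, model)

    if len(calls) > 2:
        return _finish(
            data.subject_id, None, ["gel"], costs,
            status="incomplete", notes=["more than two gel bands: artifact lane"],
        )

    if len(calls) == 2:
        sep = bands[1][0] - bands[0][0]
        within_normal = all(b[0] <= rule.str_normal_max_bp for b in bands)
        if within_normal and sep >= gel_ambiguity_bp:
            a, b = sorted(calls, key=lambda c: c.repeat_count)
            return _finish(
                data.subject_id,
                ExpansionGenotype(GenotypeClass.NN, a, b),
                ["gel"],
                costs,
            )
        note = (
            "gel bands in close proximity" if sep < gel_ambiguity_bp
            else "gel band beyond the normal size range"
        )
        return _escalate(data, calls, model, rule, params, costs, note)

    if len(calls) == 1:
        return _escalate(
            data, calls, model, rule, params, costs,
            "single gel band: homozygote or expanded-allele dropout",
        )
    return _escalate(
        data, [], model, rule, params, costs,
        "no gel band: suspected biallelic dropout (X/X)",
    )


def _escalate(
    data: AssayData,
    gel_calls: list[AlleleCall],
    model: SizingModel,
    rule: ClassificationRule,
    params: CallerParams,
    costs: CostConfig,
    note: str,
) -> WorkflowResult:
    assays = ["gel", "tp_fragment"]
    tp_clusters = segment_tp_ladder(data.tp_table, model, params)
    if not gel_calls and not tp_clusters:
        return _finish(
            data.subject_id, None, assays, costs,
            status="incomplete", escalated=True, notes=[note, "TP assay failure"],
        )
    try:
        genotype = genotype_from_assays(gel_calls, tp_clusters, rule, params)
    except DiscordanceError as exc:
        return _finish(
            data.subject_id, None, assays, costs,
            status="discordant", escalated=True, notes=[note, str(exc)],
        )
    return _finish(
        data.subject_id, genotype, assays, costs, escalated=True, notes=[note]
    )


@dataclass
class WorkflowComparison:
    n_samples: int
    n_concordant: int
    concordance: float  # fraction with identical collapsed genotype class
    cost_established: float
    cost_proposed: float
    cost_saved: float
    n_gel_only: int  # proposed samples settled by the gel alone
    n_escalations: int
    n_ambiguity_escalations: int  # escalations caused by close gel bands
    discordant_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_concordant": self.n_concordant,
            "concordance": self.concordance,
            "cost_established": self.cost_established,
            "cost_proposed": self.cost_proposed,
            "cost_saved": self.cost_saved,
            "n_gel_only": self.n_gel_only,
            "n_escalations": self.n_escalations,
            "n_ambiguity_escalations": self.n_ambiguity_escalations,
            "discordant_samples": list(self.discordant_samples),
        }


def compare_workflows(
    cohort: list[AssayData],
    model: SizingModel = SizingModel(),
    rule: ClassificationRule = ClassificationRule(),
    params: CallerParams = CallerParams(),
    costs: CostConfig = CostConfig(),
) -> WorkflowComparison:
    """Run both algorithms on every sample and tabulate agreement and cost.

    Concordance compares collapsed genotype classes (the homozygous N/N
    candidate counts as N/N on both paths); samples on which either path
    failed outright count as non-concordant and are listed.
    """
    n_conc = 0
    cost_est = cost_prop = 0.0
    n_gel_only = n_escal = n_ambig = 0
    discordant: list[str] = []
    for data in cohort:
        est = run_established(data, model, rule, params, costs)
        prop = run_proposed(data, model, rule, params, costs)
        cost_est += est.cost_units
        cost_prop += prop.cost_units
        if prop.escalated:
            n_escal += 1
            if any("close proximity" in n for n in prop.notes):
                n_ambig += 1
        else:
            n_gel_only += 1
        if (
            est.genotype is not None
            and prop.genotype is not None
            and est.genotype.genotype_class.collapsed
            == prop.genotype.genotype_class.collapsed
        ):
            n_conc += 1
        else:
            discordant.append(data.subject_id)
    n = len(cohort)
    return WorkflowComparison(
        n_samples=n,
        n_concordant=n_conc,
        concordance=n_conc / n if n else float("nan"),
        cost_established=cost_est,
        cost_proposed=cost_prop,
        cost_saved=cost_est - cost_prop,
        n_gel_only=n_gel_only,
        n_escalations=n_escal,
        n_ambiguity_escalations=n_ambig,
        discordant_samples=discordant,
    )
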