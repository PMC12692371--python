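"""Peak-table interpretation: from sized fragment-analysis peaks to an
expansion genotype.

Input is the sized peak list of one capillary injection (or the band list of
one gel lane); raw trace parsing and size-standard fitting belong to the
instrument software and are out of scope.  The caller

1. filters and merges STR-PCR peaks into at most two allelic product calls,
2. chains TP-PCR peaks into 3 bp-spaced ladders and segments them into
   per-allele clusters at intensity step-downs,
3. combines both assays into one of the genotype classes N/N, N/X, X/X, or
   a homozygous N/N candidate that needs sequencing confirmation.

Expanded (X) alleles usually fail STR-PCR (allelic dropout), so their
repeat count comes from the TP ladder extent alone and is right-censored:
the ladder fades into the noise floor, making the estimate a lower bound.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

from .sizing import (
    ClassificationRule,
    SizingModel,
    is_pathological,
    str_size_to_repeats,
    tp_size_to_repeats,
)

__all__ = [
    "Assay",
    "GenotypeClass",
    "CallMethod",
    "Peak",
    "PeakTable",
    "GelLane",
    "AlleleCall",
    "LadderCluster",
    "ExpansionGenotype",
    "CallerParams",
    "ContaminationError",
    "DiscordanceError",
    "call_str_alleles",
    "segment_tp_ladder",
    "genotype_from_assays",
    "concordance_check",
    "ConcordanceResult",
]


class Assay(str, enum.Enum):
    STR = "STR"
    TP = "TP"


class GenotypeClass(str, enum.Enum):
    NN = "N/N"
    NX = "N/X"
    XX = "X/X"
    NN_HOMOZYGOUS_CANDIDATE = "N/N-homozygous-candidate"

    @property
    def collapsed(self) -> "GenotypeClass":
        """Class used by downstream statistics (candidate counts as N/N)."""
        if self is GenotypeClass.NN_HOMOZYGOUS_CANDIDATE:
            return GenotypeClass.NN
        return self


class CallMethod(str, enum.Enum):
    GEL = "gel"
    STR_FRAGMENT = "str_fragment"
    TP_LADDER_COUNT = "tp_ladder_count"
    TP_LAST_PEAK = "tp_last_peak"


class ContaminationError(ValueError):
    """More STR allelic products than a diploid sample can produce."""


class DiscordanceError(ValueError):
    """STR-PCR and TP-PCR evidence contradict; sample needs manual review."""


@dataclass(frozen=True)
class Peak:
    size_bp: float
    height: float

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("peak size must be positive")
        if self.height < 0:
            raise ValueError("peak height must be non-negative")


@dataclass
class PeakTable:
    """Sized peaks of one sample x assay injection, ascending by size."""

    sample_id: str
    assay: Assay
    peaks: list[Peak]
    dye: str = "FAM"

    def __post_init__(self) -> None:
        self.assay = Assay(self.assay)
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)


@dataclass
class GelLane:
    """Approximate band sizes of one sample's STR-PCR gel lane."""

    sample_id: str
    bands: list[tuple[float, float]]  # (approx size bp, intensity)


@dataclass(frozen=True)
class AlleleCall:
    """An inferred per-allele repeat count with provenance.

    ``censored`` marks a lower-bound estimate: the allele's TP ladder faded
    below the detection floor before its true end, so the repeat count may
    exceed ``repeat_count``.  Only ladder-derived calls can be censored.
    """

    repeat_count: int
    size_bp: float
    method: CallMethod
    censored: bool = False
    residual_bp: float = 0.0
    sizing_warning: bool = False

    def __post_init__(self) -> None:
        if self.repeat_count < 1:
            raise ValueError("repeat count must be >= 1")
        if self.censored and self.method not in (
            CallMethod.TP_LADDER_COUNT,
            CallMethod.TP_LAST_PEAK,
        ):
            raise ValueError("only TP-ladder estimates can be censored")


@dataclass
class LadderCluster:
    """A contiguous run of TP ladder rungs attributed to one allele set."""

    member_peaks: list[Peak]
    first_size_bp: float
    last_size_bp: float
    inferred_repeats: int
    censored: bool = False
    residual_bp: float = 0.0
    sizing_warning: bool = False
    count_discrepancy: bool = False  # rung-count vs last-peak estimators disagree


@dataclass
class ExpansionGenotype:
    genotype_class: GenotypeClass
    allele1: AlleleCall | None = None
    allele2: AlleleCall | None = None
    needs_sequencing: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def allele_repeats(self) -> tuple[int | None, int | None]:
        return (
            self.allele1.repeat_count if self.allele1 else None,
            self.allele2.repeat_count if self.allele2 else None,
        )


@dataclass(frozen=True)
class CallerParams:
    """Peak-filtering and segmentation thresholds (instrument-dependent).

    ``min_rel_height``: STR peaks below this fraction of the tallest peak
    are treated as stutter/noise.  ``merge_tol_bp``: peaks closer than this
    are one product sized twice.  ``spacing_tol_bp``: accepted deviation of
    ladder rung spacing from 3 bp.  ``cluster_drop_ratio``: a rung whose
    height falls below this fraction of the running cluster median opens a
    new cluster (an allele boundary roughly halves the rung height).
    ``noise_floor``: absolute height below which TP rungs are invisible.
    ``censor_margin``: terminal rungs within this multiple of the noise
    floor mean the ladder is fading out, so the terminal estimate is
    censored.  ``concordance_tol_repeats``: allowed repeat-count gap between
    STR and TP estimates of the same allele before evidence is declared
    discordant.  ``max_bridged_rungs``: a ladder may skip this many
    consecutive sub-floor rungs and still continue (an analyst reading the
    trace bridges an isolated dropped rung by eye; two missing rungs in a
    row end the ladder).
    """

    min_rel_height: float = 0.05
    merge_tol_bp: float = 1.5
    spacing_tol_bp: float = 0.8
    cluster_drop_ratio: float = 0.65
    noise_floor: float = 20.0
    censor_margin: float = 3.0
    concordance_tol_repeats: int = 3
    max_bridged_rungs: int = 1


def _merge_close_peaks(peaks: list[Peak], tol_bp: float) -> list[Peak]:
    """Height-weighted merge of peaks within ``tol_bp`` of each other."""
    merged: list[Peak] = []
    group: list[Peak] = []
    for p in peaks:
        if group and p.size_bp - group[-1].size_bp > tol_bp:
            merged.append(_weighted_peak(group))
            group = []
        group.append(p)
    if group:
        merged.append(_weighted_peak(group))
    return merged


def _weighted_peak(group: list[Peak]) -> Peak:
    h = sum(p.height for p in group)
    if h == 0:
        size = float(np.mean([p.size_bp for p in group]))
    else:
        size = sum(p.size_bp * p.height for p in group) / h
    return Peak(size_bp=size, height=h)


def call_str_alleles(
    table: PeakTable,
    model: SizingModel = SizingModel(),
    params: CallerParams = CallerParams(),
) -> list[AlleleCall]:
    """Call 0, 1 or 2 allelic products from an STR-PCR peak table.

    Low peaks (below ``min_rel_height`` of the tallest) are dropped; peaks
    within the merge tolerance are combined height-weighted; each surviving
    peak is converted to a repeat count.  An empty result is *not* an
    error: it is the signature of biallelic dropout (possible X/X).
    """
    if table.assay is not Assay.STR:
        raise ValueError(f"expected an STR peak table, got {table.assay}")
    if not table.peaks:
        return []
    top = max(p.height for p in table.peaks)
    survivors = [p for p in table.peaks if p.height >= params.min_rel_height * top]
    survivors = _merge_close_peaks(survivors, params.merge_tol_bp)
    if len(survivors) > 2:
        raise ContaminationError(
            f"sample {table.sample_id}: {len(survivors)} STR products after "
            "filtering; diploid samples yield at most two (contamination or artifacts)"
        )
    calls = []
    for p in survivors:
        est = str_size_to_repeats(p.size_bp, model)
        calls.append(
            AlleleCall(
                repeat_count=est.repeats,
                size_bp=p.size_bp,
                method=CallMethod.STR_FRAGMENT,
                residual_bp=est.residual_bp,
                sizing_warning=est.sizing_warning,
            )
        )
    return calls


def segment_tp_ladder(
    table: PeakTable,
    model: SizingModel = SizingModel(),
    params: CallerParams = CallerParams(),
) -> list[LadderCluster]:
    """Chain TP-PCR peaks into a ladder and split it into allele clusters.

    Peaks above the noise floor are chained while consecutive spacing stays
    within ``3 +/- spacing_tol_bp``; within a chain, a step-down below
    ``cluster_drop_ratio`` of the running cluster median opens a new
    cluster (one allele's ladder ended).  Each cluster's repeat count is
    taken from its terminal rung size; the rung-count estimate is kept as a
    cross-check and any disagreement is flagged.  The final cluster is
    censored when its terminal rungs approach the noise floor.
    """
    if table.assay is not Assay.TP:
        raise ValueError(f"expected a TP peak table, got {table.assay}")
    peaks = [p for p in table.peaks if p.height >= params.noise_floor]
    if not peaks:
        return []

    # chain into ladders; keep only the longest chain (stray peaks are noise)
    chains: list[list[Peak]] = [[peaks[0]]]
    for p in peaks[1:]:
        gap = p.size_bp - chains[-1][-1].size_bp
        bridged = any(
            abs(gap - (1 + skip) * model.triplet_bp) <= params.spacing_tol_bp
            for skip in range(params.max_bridged_rungs + 1)
        )
        if bridged:
            chains[-1].append(p)
        else:
            chains.append([p])
    ladder = max(chains, key=len)
    if len(ladder) < 2 and len(peaks) > 1:
        return []  # no ladder structure above the floor: assay failure

    # segment at intensity step-downs; the reference level is the median of
    # the trailing few rungs, so geometric decay along a long cluster does
    # not itself trip the detector (an allele boundary halves the level)
    clusters: list[list[Peak]] = [[ladder[0]]]
    for p in ladder[1:]:
        tail = clusters[-1][-5:]
        med = float(np.median([q.height for q in tail]))
        if p.height < params.cluster_drop_ratio * med:
            clusters.append([p])
        else:
            clusters[-1].append(p)

    out: list[LadderCluster] = []
    rung_offset = 0  # rungs in preceding clusters
    first_est = tp_size_to_repeats(ladder[0].size_bp, model)
    for i, members in enumerate(clusters):
        last = members[-1]
        est = tp_size_to_repeats(last.size_bp, model)
        # count-based estimate: rungs seen so far anchored at the first rung
        rung_offset += len(members)
        count_estimate = first_est.repeats - 1 + rung_offset
        is_last = i == len(clusters) - 1
        censored = is_last and last.height <= params.censor_margin * params.noise_floor
        out.append(
            LadderCluster(
                member_peaks=list(members),
                first_size_bp=members[0].size_bp,
                last_size_bp=last.size_bp,
                inferred_repeats=est.repeats,
                censored=censored,
                residual_bp=est.residual_bp,
                sizing_warning=est.sizing_warning,
                count_discrepancy=count_estimate != est.repeats,
            )
        )
    return out


def _cluster_call(cluster: LadderCluster, censored: bool) -> AlleleCall:
    return AlleleCall(
        repeat_count=cluster.inferred_repeats,
        size_bp=cluster.last_size_bp,
        method=CallMethod.TP_LAST_PEAK,
        censored=censored,
        residual_bp=cluster.residual_bp,
        sizing_warning=cluster.sizing_warning,
    )


def genotype_from_assays(
    str_calls: list[AlleleCall] | None,
    tp_clusters: list[LadderCluster] | None,
    rule: ClassificationRule = ClassificationRule(),
    params: CallerParams = CallerParams(),
) -> ExpansionGenotype:
    """Adjudicate an expansion genotype from STR calls and TP clusters.

    Decision table (cutoff = ``rule.pathological_cutoff_triplets``):

    * two STR calls, both normal, TP (if present) not extending beyond
      them -> **N/N**;
    * one STR call + TP ladder extending past the cutoff -> **N/X**, the
      expanded allele estimated from the terminal cluster and censored
      (ladder extent is a lower bound);
    * no STR product + TP ladder past the cutoff -> **X/X**, both alleles
      censored;
    * one STR call + a single TP cluster matching it within one repeat ->
      **N/N homozygous candidate**, to be confirmed by sequencing;
    * one STR call + several TP clusters, all normal -> **N/N** with the
      second allele taken from the ladder (arises when a gel lane merged
      two close bands).

    Contradictions (TP far beyond two normal STR calls, a normal-only
    ladder with no STR product, ...) raise :class:`DiscordanceError` for
    manual review rather than guessing.
    """
    str_calls = list(str_calls or [])
    tp_clusters = list(tp_clusters or [])
    if not str_calls and not tp_clusters:
        raise ValueError("at least one assay's data must be present")
    cutoff = rule.pathological_cutoff_triplets
    tol = params.concordance_tol_repeats

    tp_max = max((c.inferred_repeats for c in tp_clusters), default=None)

    if len(str_calls) == 2:
        a, b = sorted(str_calls, key=lambda c: c.repeat_count)
        warnings = []
        if any(is_pathological(c.repeat_count, rule) for c in (a, b)):
            # an expanded allele that survived STR-PCR: still N/X or X/X
            n_path = sum(is_pathological(c.repeat_count, rule) for c in (a, b))
            cls = GenotypeClass.XX if n_path == 2 else GenotypeClass.NX
            return ExpansionGenotype(cls, a, b, warnings=["expanded allele amplified in STR-PCR"])
        if tp_max is not None and tp_max > b.repeat_count + tol:
            raise DiscordanceError(
                f"TP ladder reaches {tp_max} repeats but both STR alleles are "
                f"{a.repeat_count}/{b.repeat_count}"
            )
        return ExpansionGenotype(GenotypeClass.NN, a, b, warnings=warnings)

    if len(str_calls) == 1:
        n_call = str_calls[0]
        if not tp_clusters:
            # single product, no ladder data: cannot distinguish homozygote
            # from dropout; flag for follow-up
            return ExpansionGenotype(
                GenotypeClass.NN_HOMOZYGOUS_CANDIDATE,
                n_call,
                None,
                needs_sequencing=True,
                warnings=["no TP data; homozygosity unconfirmed"],
            )
        terminal = tp_clusters[-1]
        if tp_max is not None and tp_max > cutoff:
            if is_pathological(n_call.repeat_count, rule):
                raise DiscordanceError("single STR product already exceeds the cutoff")
            return ExpansionGenotype(
                GenotypeClass.NX,
                n_call,
                _cluster_call(terminal, censored=True),
            )
        if len(tp_clusters) == 1:
            if abs(terminal.inferred_repeats - n_call.repeat_count) <= 1:
                return ExpansionGenotype(
                    GenotypeClass.NN_HOMOZYGOUS_CANDIDATE,
                    n_call,
                    _cluster_call(terminal, censored=False),
                    needs_sequencing=True,
                )
            raise DiscordanceError(
                f"single STR product of {n_call.repeat_count} repeats vs single "
                f"TP cluster of {terminal.inferred_repeats}"
            )
        # several clusters, all normal: second allele from the ladder
        others = [c for c in tp_clusters if abs(c.inferred_repeats - n_call.repeat_count) > 1]
        second = others[-1] if others else tp_clusters[-1]
        return ExpansionGenotype(
            GenotypeClass.NN,
            n_call,
            _cluster_call(second, censored=False),
            warnings=["second allele inferred from TP ladder only"],
        )

    # no STR product at all: biallelic dropout
    if tp_max is None:
        raise DiscordanceError("no STR product and no TP ladder: assay failure")
    if tp_max <= cutoff:
        raise DiscordanceError(
            f"no STR product yet the TP ladder stops at {tp_max} repeats (normal range)"
        )
    # both alleles expanded; the lower allele's boundary is the last cluster
    # break past the cutoff (earlier breaks can be intensity noise), and
    # with a single cluster both alleles share the terminal estimate
    expanded = [c for c in tp_clusters[:-1] if c.inferred_repeats > cutoff]
    lower = expanded[-1] if expanded else tp_clusters[-1]
    a1 = _cluster_call(lower, censored=True)
    a2 = _cluster_call(tp_clusters[-1], censored=True)
    return ExpansionGenotype(GenotypeClass.XX, a1, a2)


@dataclass
class ConcordanceResult:
    rho: float
    p_value: float
    deltas: dict[str, list[int]]  # per-sample TP-minus-STR repeat deltas
    unpaired: dict[str, int]  # sample -> number of unpairable estimates


def concordance_check(
    per_sample: dict[str, tuple[list[AlleleCall], list[LadderCluster]]],
) -> ConcordanceResult:
    """Spearman rank correlation between paired STR and TP repeat estimates.

    For each sample, STR calls and TP clusters are sorted by repeat count
    and paired positionally; leftovers are counted as unpaired (and
    reported, never silently dropped).  The correlation pools all pairs in
    the batch.
    """
    str_vals: list[int] = []
    tp_vals: list[int] = []
    deltas: dict[str, list[int]] = {}
    unpaired: dict[str, int] = {}
    for sid, (calls, clusters) in per_sample.items():
        s = sorted(c.repeat_count for c in calls)
        t = sorted(c.inferred_repeats for c in clusters)
        k = min(len(s), len(t))
        if len(s) != len(t):
            unpaired[sid] = abs(len(s) - len(t))
        if k == 0:
            continue
        # pair ascending and keep the smallest k of each: an allele missing
        # from STR is the dropped expanded one, i.e. the largest TP cluster
        # is the one left unpaired
        s_sel, t_sel = s[:k], t[:k]
        str_vals.extend(s_sel)
        tp_vals.extend(t_sel)
        deltas[sid] = [tv - sv for sv, tv in zip(s_sel, t_sel)]
    if len(str_vals) < 2:
        raise ValueError("need at least two paired estimates for a correlation")
    rho, p = _scipy_stats.spearmanr(str_vals, tp_vals)
    return ConcordanceResult(rho=float(rho), p_value=float(p), deltas=deltas, unpaired=unpaired)
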