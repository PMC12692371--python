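"""Fragment-size arithmetic for the *TCF4* CTG18.1 trinucleotide repeat.

Two PCR assays size the CTG tract:

* **STR-PCR** amplifies across the repeat with flanking primers, so the
  product grows by 3 bp per CTG triplet on top of a fixed flanking length.
  With the default sizing model an allele of *n* repeats yields a product of
  ``114 + 3n`` bp (11 repeats -> 147 bp; 40 repeats -> 234 bp, just under
  the 235 bp normal/pathological size threshold).

* **TP-PCR** (triplet-repeat primed PCR) uses a reverse primer whose 3' end
  is complementary to five consecutive CTG triplets, so it anneals at every
  in-register position inside the tract.  An allele of *n* repeats therefore
  produces a ladder of ``n - 4`` products spaced 3 bp apart; the shortest
  rung (primer anchored at the first five triplets) runs at ``54 + 15 = 69``
  bp and the terminal rung at ``54 + 3n`` bp.  The ladder's extent reveals
  the repeat count even when the expanded allele fails STR-PCR entirely.

Alleles with more than 40 triplets are classed pathological (symbol X);
alleles at or below 40 are normal (symbol N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SizingModel",
    "ClassificationRule",
    "RepeatEstimate",
    "SIZING_WARN_RESIDUAL_BP",
    "str_product_size",
    "str_size_to_repeats",
    "tp_ladder_sizes",
    "tp_size_to_repeats",
    "is_pathological",
]

TRIPLET_BP = 3

#: Rounding residual (bp) above which a size->repeat conversion is flagged
#: as suspect: half a triplet is the point where nearest-integer rounding
#: can no longer be trusted, so we warn at 1.5 bp.
SIZING_WARN_RESIDUAL_BP = 1.5


@dataclass(frozen=True)
class SizingModel:
    """Nominal linear model linking repeat count to product size.

    Parameters
    ----------
    str_offset_bp
        Length of the STR-PCR product minus the repeat tract (flanking
        sequence plus primers), in bp.
    tp_offset_bp
        Fixed (non-repeat) length of a TP-PCR product, in bp.
    tp_anchor_triplets
        Number of CTG triplets complementary to the 3' end of the TP
        reverse primer; the shortest ladder rung corresponds to the primer
        anchored at the first ``tp_anchor_triplets`` triplets.
    """

    str_offset_bp: float = 114.0
    tp_offset_bp: float = 54.0
    triplet_bp: int = TRIPLET_BP
    tp_anchor_triplets: int = 5

    def __post_init__(self) -> None:
        if self.triplet_bp != TRIPLET_BP:
            raise ValueError("CTG repeats advance product size by 3 bp per unit")
        if self.tp_anchor_triplets != 5:
            raise ValueError("the TP primer anchors five CTG triplets")
        if self.str_offset_bp <= 0 or self.tp_offset_bp <= 0:
            raise ValueError("sizing offsets must be strictly positive")


@dataclass(frozen=True)
class ClassificationRule:
    """Normal/pathological classification of a repeat count.

    ``pathological_cutoff_triplets`` is a strict threshold: an allele is
    pathological (X) iff it carries *more* than this many triplets.
    ``str_normal_max_bp`` is the equivalent STR-PCR product-size threshold
    (inclusive) used when only a band size is available.
    """

    pathological_cutoff_triplets: int = 40
    str_normal_max_bp: float = 235.0

    def validate(self, model: SizingModel) -> None:
        """Check that the bp threshold matches the repeat cutoff within one triplet."""
        nominal = str_product_size(self.pathological_cutoff_triplets, model)
        if abs(self.str_normal_max_bp - nominal) > model.triplet_bp:
            raise ValueError(
                f"str_normal_max_bp={self.str_normal_max_bp} inconsistent with "
                f"cutoff {self.pathological_cutoff_triplets} repeats "
                f"({nominal} bp nominal)"
            )


@dataclass(frozen=True)
class RepeatEstimate:
    """A repeat count inferred from a measured fragment size.

    ``residual_bp`` is the signed distance from the measured size to the
    nominal size of the rounded repeat count; ``sizing_warning`` is set when
    its magnitude exceeds :data:`SIZING_WARN_RESIDUAL_BP`, i.e. the
    measurement sits closer to the midpoint between two repeat rungs than
    capillary sizing error should allow.
    """

    repeats: int
    residual_bp: float
    sizing_warning: bool = field(default=False)


def str_product_size(n: int, model: SizingModel = SizingModel()) -> float:
    """Nominal STR-PCR product size (bp) for an allele of ``n`` CTG repeats."""
    if n < 1:
        raise ValueError(f"repeat count must be >= 1, got {n}")
    return model.str_offset_bp + model.triplet_bp * n


def _size_to_repeats(size_bp: float, offset_bp: float, triplet_bp: int) -> RepeatEstimate:
    if size_bp <= offset_bp:
        raise ValueError(
            f"product size {size_bp} bp does not exceed the {offset_bp} bp offset"
        )
    n = round((size_bp - offset_bp) / triplet_bp)
    n = max(n, 1)
    residual = size_bp - (offset_bp + triplet_bp * n)
    return RepeatEstimate(
        repeats=n,
        residual_bp=residual,
        sizing_warning=abs(residual) > SIZING_WARN_RESIDUAL_BP,
    )


def str_size_to_repeats(size_bp: float, model: SizingModel = SizingModel()) -> RepeatEstimate:
    """Invert :func:`str_product_size` with nearest-integer rounding.

    147 bp -> 11 repeats; 235 bp -> 40 repeats (residual 1 bp).
    """
    return _size_to_repeats(size_bp, model.str_offset_bp, model.triplet_bp)


def tp_ladder_sizes(n: int, model: SizingModel = SizingModel()) -> list[float]:
    """Nominal TP-PCR ladder rung sizes (bp) for an allele of ``n`` repeats.

    Returns one rung per in-register annealing position of the five-triplet
    primer anchor, i.e. ``n - 4`` sizes for ``n >= 5``: ``tp_offset + 3k``
    for ``k = 5 .. n``.  For ``n < 5`` there is no annealing site and the
    ladder is empty (normal human alleles carry >= 10 triplets, so this is
    a degenerate input rather than an error).
    """
    if n < 1:
        raise ValueError(f"repeat count must be >= 1, got {n}")
    return [
        model.tp_offset_bp + model.triplet_bp * k
        for k in range(model.tp_anchor_triplets, n + 1)
    ]


def tp_size_to_repeats(
    last_peak_size_bp: float, model: SizingModel = SizingModel()
) -> RepeatEstimate:
    """Repeat count implied by the terminal (largest) TP-PCR ladder rung.

    87 bp -> 11 repeats; 452 bp -> 133 repeats (residual -1 bp).
    """
    return _size_to_repeats(last_peak_size_bp, model.tp_offset_bp, model.triplet_bp)


def is_pathological(n: int, rule: ClassificationRule = ClassificationRule()) -> bool:
    """True iff an allele of ``n`` repeats is an expanded (X) allele: n > cutoff."""
    if n < 1:
        raise ValueError(f"repeat count must be >= 1, got {n}")
    return n > rule.pathological_cutoff_triplets
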