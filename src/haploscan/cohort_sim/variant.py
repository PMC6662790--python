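"""Planting an unmeasured rare variant on one founder haplotype.

The variant never enters the marker set: carrier status exists only in the
truth record, which is exactly the situation the haplotype scan is for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..datatypes import FocalVariant
from ..errors import ValidationError
from .genedrop import TruthIBD

__all__ = ["PlantedVariant", "plant_variant"]


@dataclass
class PlantedVariant:
    """Truth record of a planted variant: who carries it, and on which
    haplotype(s)."""

    chrom: str
    position_bp: int
    founder_hap_label: int
    carrier_ids: list[str]
    carrier_haps: dict[str, list[int]] = field(default_factory=dict)

    def as_focal(self, known_carrier_ids: list[str] | None = None) -> FocalVariant:
        """The analysis-side view: position plus a (possibly partial) set of
        known carriers."""
        known = self.carrier_ids if known_carrier_ids is None else known_carrier_ids
        return FocalVariant(self.chrom, self.position_bp, list(known))


def plant_variant(
    truth: TruthIBD,
    founder_hap_label: int,
    chrom: str,
    position_bp: int,
    n_founders: int | None = None,
) -> PlantedVariant:
    """Mark every individual whose truth segment covering ``position_bp``
    traces to ``founder_hap_label`` as a carrier."""
    lengths = dict(truth.genome)
    if chrom not in lengths:
        raise ValidationError(f"unknown chromosome {chrom!r}")
    if not (1 <= position_bp <= lengths[chrom]):
        raise ValidationError(
            f"position {position_bp} outside chromosome {chrom!r} (1..{lengths[chrom]})"
        )
    if n_founders is not None and not (0 <= founder_hap_label < 2 * n_founders):
        raise ValidationError(f"unknown founder haplotype label {founder_hap_label}")

    coord = position_bp - 1
    seen_labels: set[int] = set()
    carriers: list[str] = []
    carrier_haps: dict[str, list[int]] = {}
    for ind in truth.ids:
        haps = []
        for hap in (0, 1):
            label = truth.label_at(ind, chrom, hap, coord)
            seen_labels.add(label)
            if label == founder_hap_label:
                haps.append(hap)
        if haps:
            carriers.append(ind)
            carrier_haps[ind] = haps
    if n_founders is None and founder_hap_label not in seen_labels and not carriers:
        # Without a founder count we can at least reject labels that no
        # founder in this truth set carries anywhere at the locus.
        all_labels = {
            seg[2]
            for ind in truth.ids
            for hap in (0, 1)
            for seg in truth.of(ind, chrom, hap)
        }
        if founder_hap_label not in all_labels:
            raise ValidationError(
                f"unknown founder haplotype label {founder_hap_label}"
            )
    return PlantedVariant(chrom, position_bp, founder_hap_label, carriers, carrier_haps)
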