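"""Antibody marker panel.

A panel lists the markers measured per cell, the role each plays in the
analysis (lineage markers define cell types, functional markers define
activity states, DNA and segmentation channels are carried as metadata),
and the cellular compartment the signal is read from.  YAP1 is the one
marker scored on the nuclear compartment: its activity is nuclear
localisation, so whole-cell signal would conflate active and sequestered
protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError

ROLES = ("lineage", "functional", "segmentation", "dna")
COMPARTMENTS = ("whole-cell", "nuclear")


@dataclass(frozen=True)
class MarkerDef:
    """One marker: name, analysis role, and readout compartment."""

    name: str
    role: str
    compartment: str = "whole-cell"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown marker role {self.role!r} for {self.name}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r} for {self.name}"
            )


class MarkerPanel:
    """Ordered, validated collection of :class:`MarkerDef`.

    Invariants: names unique; at least one lineage and one functional
    marker; YAP1, when present, is nuclear.
    """

    def __init__(self, markers: Sequence[MarkerDef]):
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate marker names: {dupes}")
        roles = {m.role for m in markers}
        if "lineage" not in roles or "functional" not in roles:
            raise ValidationError("panel needs at least one lineage and one functional marker")
        for m in markers:
            if m.name == "YAP1" and m.compartment != "nuclear":
                raise ValidationError("YAP1 must be scored on the nuclear compartment")
        self._markers = tuple(markers)
        self._by_name = {m.name: m for m in markers}

    def __len__(self) -> int:
        return len(self._markers)

    def __iter__(self) -> Iterable[MarkerDef]:
        return iter(self._markers)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> MarkerDef:
        return self._by_name[name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerPanel) and self._markers == other._markers

    @property
    def names(self) -> list[str]:
        return [m.name for m in self._markers]

    def names_by_role(self, role: str) -> list[str]:
        return [m.name for m in self._markers if m.role == role]

    @property
    def lineage(self) -> list[str]:
        return self.names_by_role("lineage")

    @property
    def functional(self) -> list[str]:
        return self.names_by_role("functional")

    @property
    def nuclear(self) -> list[str]:
        """Markers read from the nuclear compartment."""
        return [m.name for m in self._markers if m.compartment == "nuclear"]

    @classmethod
    def default(cls) -> "MarkerPanel":
        """The default 38-marker panel used throughout the package.

        Mirrors a typical FFPE tissue IMC panel for oral mucosa: epithelial
        (E-cadherin, EGFR, pan-cytokeratin), endothelial (CD31, Podoplanin,
        CD140b, CD146, CD34, LYVE1), stromal (Collagen1, CD90, aSMA,
        Vimentin, FSP1), immune lineage (CD68, CD163, CD20, CD4, CD8a,
        FoxP3, CD56, CD11c, HLADR, Arginase1), nine functional markers,
        two DNA intercalators and three opaque segmentation channels.
        """
        lineage = [
            "Ecad", "EGFR", "PanCK",
            "CD31", "Podoplanin", "CD140b", "CD146", "CD34", "LYVE1",
            "Collagen1", "CD90", "aSMA", "Vimentin", "FSP1",
            "CD68", "CD163", "CD20", "CD4", "CD8a", "FoxP3", "CD56",
            "CD11c", "HLADR", "Arginase1",
        ]
        functional = [
            "Ki67", "pERK", "BNIP3", "Caveolin", "pNFkB",
            "IntegrinB1", "pSTAT3", "PD1",
        ]
        defs = [MarkerDef(n, "lineage") for n in lineage]
        defs += [MarkerDef(n, "functional") for n in functional]
        defs.append(MarkerDef("YAP1", "functional", compartment="nuclear"))
        defs += [MarkerDef(n, "dna") for n in ("DNA1", "DNA2")]
        defs += [MarkerDef(n, "segmentation") for n in ("Seg1", "Seg2", "Seg3")]
        return cls(defs)
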