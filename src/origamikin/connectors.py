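"""Connector-strand designs and the effective-association-rate model.

Membrane-anchored DNA-origami monomers are cross-linked by connector
oligonucleotides. Two design families are modeled:

* **scaffold connectors** — high-complexity sequences hybridizing directly to
  scaffold loops of two monomers; site- and orientation-specific, a single
  binding register, and prone to internal hairpins that reduce accessibility.
* **repeat connectors** — low-complexity (oligo-T) strands binding short
  homopolymer staple extensions (the A7 docking extension). A sticker of
  ``L_s`` nt offers ``L_s - L_d + 1`` alignment registers ("reading frames")
  against an ``L_d``-nt docking extension, raising the effective local
  concentration of binding sites.

The effective on-rate is modeled as the product

    k_eff = k_base * n_frames * hairpin_accessibility * valence_multiplier

the simplest law consistent with the two mechanisms above (register
multiplicity and hairpin suppression). All factors are user-configurable;
hairpin accessibility is an input, never predicted from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

__all__ = [
    "DockingSpec",
    "ConnectorSpec",
    "RateModel",
    "reading_frames",
    "max_simultaneous_occupancy",
    "effective_on_rate",
    "edge_link_rate",
]


@dataclass(frozen=True)
class DockingSpec:
    """Docking-extension geometry on the origami monomer.

    Defaults describe a monomer with A7 staple extensions, four connector
    sites per linkable edge and two linkable (cross-linking) edges.
    """

    motif_base: str = "A"
    extension_length: int = 7
    sites_per_edge: int = 4
    linkable_edges: int = 2

    def __post_init__(self) -> None:
        if len(self.motif_base) != 1 or not self.motif_base.isalpha():
            raise ValueError("motif_base must be a single nucleotide letter")
        if self.extension_length < 1:
            raise ValueError("extension_length must be >= 1")
        if self.sites_per_edge < 1:
            raise ValueError("sites_per_edge must be >= 1")
        if self.linkable_edges not in (1, 2):
            raise ValueError("linkable_edges must be 1 or 2")

    def to_config(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ConnectorSpec:
    """One connector-strand design.

    ``sticker_length`` is the terminal binding stretch per end. For all-T
    connectors (``spacer_length == 0``) there is no inert spacer: any register
    along the full strand may serve either binding partner, so the per-end
    binding length is the total length (see :func:`binding_length`).
    """

    kind: Literal["scaffold", "repeat"]
    total_length: int
    sticker_length: int
    spacer_length: int = 0
    concentration_nM: float = 250.0
    orientation_specific: bool = False
    flexible_linker: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("scaffold", "repeat"):
            raise ValueError(f"unknown connector kind {self.kind!r}")
        if self.sticker_length < 1 or self.total_length < 1:
            raise ValueError("lengths must be >= 1")
        if self.sticker_length > self.total_length:
            raise ValueError("sticker_length must not exceed total_length")
        if self.spacer_length < 0:
            raise ValueError("spacer_length must be >= 0")
        if self.spacer_length > 0 and (
            self.total_length != 2 * self.sticker_length + self.spacer_length
        ):
            raise ValueError(
                "with a spacer, total_length must equal "
                "2*sticker_length + spacer_length"
            )
        if self.concentration_nM <= 0:
            raise ValueError("concentration must be positive")
        if self.kind == "scaffold" and not self.orientation_specific:
            raise ValueError("scaffold connectors are orientation specific")

    @property
    def binding_length(self) -> int:
        """Binding stretch available per end, nt.

        With an inert spacer the sticker is the whole binding stretch;
        without one (all-T strands) any register of the full strand can bind
        either partner.
        """
        return self.sticker_length if self.spacer_length > 0 else self.total_length

    def to_config(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RateModel:
    """Parameters of the effective-association-rate law.

    base_on_rate
        Hybridization rate of a single perfectly matched register,
        per molar per second. Default 1e6 /M/s, a typical short-duplex
        on-rate.
    hairpin_accessibility
        Fraction of connectors not sequestered in internal secondary
        structure, in (0, 1]. Repeat (oligo-T) connectors cannot form
        hairpins (1.0); scaffold connectors may be penalized.
    valence_multiplier
        Dimensionless factor (>= 1) for the multiple connector sites per
        edge acting in parallel.
    """

    base_on_rate: float = 1.0e6
    hairpin_accessibility: float = 1.0
    valence_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.base_on_rate <= 0:
            raise ValueError("base_on_rate must be positive")
        if not (0.0 < self.hairpin_accessibility <= 1.0):
            raise ValueError("hairpin_accessibility must be in (0, 1]")
        if self.valence_multiplier < 1.0:
            raise ValueError("valence_multiplier must be >= 1")

    def to_config(self) -> dict:
        return asdict(self)


def reading_frames(sticker_length: int, docking_length: int) -> int:
    """Number of registers at which a docking extension is fully covered.

    A docking extension of ``docking_length`` nt can hybridize at any offset
    along a homopolymer sticker of ``sticker_length`` nt as long as it is
    fully covered, giving ``max(0, sticker_length - docking_length + 1)``
    reading frames.
    """
    if sticker_length < 1 or docking_length < 1:
        raise ValueError("lengths must be positive")
    return max(0, sticker_length - docking_length + 1)


def max_simultaneous_occupancy(connector_binding_length: int, docking_length: int) -> int:
    """Docking extensions a connector can engage without overlap.

    Short all-T connectors make docking extensions compete for overlapping
    stretches of the same strand; the non-overlapping packing bound is
    ``floor(connector_binding_length / docking_length)``.
    """
    if connector_binding_length < 1 or docking_length < 1:
        raise ValueError("lengths must be positive")
    return connector_binding_length // docking_length


def effective_on_rate(
    model: RateModel, connector: ConnectorSpec, docking: DockingSpec
) -> float:
    """Effective association rate for one connector design, per molar per second.

    ``k_eff = k_base * frames * accessibility * valence``. Scaffold connectors
    bind a unique site (one frame); repeat connectors gain one frame per extra
    sticker nucleotide beyond the docking length. A sticker shorter than the
    docking extension yields zero (no productive register), not an error.
    """
    if connector.kind == "scaffold":
        frames = 1
    else:
        frames = reading_frames(connector.binding_length, docking.extension_length)
    return (
        model.base_on_rate
        * frames
        * model.hairpin_accessibility
        * model.valence_multiplier
    )


def edge_link_rate(
    model: RateModel, connector: ConnectorSpec, docking: DockingSpec
) -> float:
    """Per-second linking rate for one eligible edge pair.

    Coarse-grains connector loading: connectors are not explicit particles;
    their solution concentration and effective on-rate fold into a single
    pseudo-first-order rate ``k_eff * [connector]`` driving edge-pair bond
    formation in the simulator.
    """
    molar = connector.concentration_nM * 1e-9
    return effective_on_rate(model, connector, docking) * molar
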