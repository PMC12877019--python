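"""Marker panel definitions for 8-plex multiplex immunofluorescence.

A panel fixes the ordered list of protein markers whose binary per-cell
positivity calls the rest of the pipeline consumes, together with the image
resolution used to convert pixel coordinates to microns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Scanner resolution of the source whole-slide images, in µm per pixel.
DEFAULT_RESOLUTION_UM_PER_PX = 0.4992

N_PANEL_MARKERS = 8


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered 8-marker mIF panel.

    Parameters
    ----------
    name
        Panel identifier, conventionally ``"lymphoid"`` or ``"myeloid"``.
    markers
        Ordered tuple of exactly 8 unique marker names. Order defines the
        column order of positivity vectors everywhere downstream.
    resolution_um_per_px
        Image resolution used when converting pixel coordinates to µm.
    """

    name: str
    markers: tuple[str, ...]
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX

    def __post_init__(self) -> None:
        if len(self.markers) != N_PANEL_MARKERS:
            raise ValueError(
                f"panel {self.name!r} must have exactly {N_PANEL_MARKERS} "
                f"markers, got {len(self.markers)}"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"panel {self.name!r} has duplicate markers")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")

    def index_of(self, marker: str) -> int:
        return self.markers.index(marker)


#: Lymphoid melanoma panel: T/B-cell lineage, immune checkpoints, melanoma
#: marker SOX10 and nitric oxide synthases iNOS/nNOS.
LYMPHOID_PANEL = MarkerPanel(
    name="lymphoid",
    markers=("CD3", "CD8", "CD20", "PD-L1", "LAG-3", "SOX10", "iNOS", "nNOS"),
)

#: Myeloid melanoma panel: monocyte/macrophage/dendritic markers, adhesion
#: marker N-Cadherin, SOX10 and synthases iNOS/eNOS.
MYELOID_PANEL = MarkerPanel(
    name="myeloid",
    markers=("CD11c", "CD14", "CD34", "MHCII", "N-Cadherin", "SOX10", "iNOS", "eNOS"),
)

PANELS: dict[str, MarkerPanel] = {p.name: p for p in (LYMPHOID_PANEL, MYELOID_PANEL)}
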