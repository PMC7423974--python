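"""Marker-panel manifest: marker names and their roles.

A panel assigns each measured channel one of three roles:

* ``lineage``  -- surface/differentiation markers used for clustering and
  gating (CD3, CD4, CD19, ...),
* ``checkpoint`` -- co-inhibitory receptors analysed for expression on
  gated subsets (PD1, TIGIT),
* ``cytokine`` -- intracellular cytokines measured after mitogenic
  stimulation (IFN-gamma, TNF-alpha, IL-17, IL-4; ASCII channel names
  ``IFNg``, ``TNFa``, ``IL17``, ``IL4``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

ROLES = ("lineage", "checkpoint", "cytokine")


@dataclass(frozen=True)
class PanelManifest:
    """Ordered marker panel with a role per marker."""

    roles: dict[str, str]

    def __post_init__(self) -> None:
        bad = {m: r for m, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown marker roles: {bad}; allowed {ROLES}")

    @property
    def markers(self) -> list[str]:
        return list(self.roles)

    def by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; allowed {ROLES}")
        return [m for m, r in self.roles.items() if r == role]

    @property
    def lineage(self) -> list[str]:
        return self.by_role("lineage")

    @property
    def checkpoint(self) -> list[str]:
        return self.by_role("checkpoint")

    @property
    def cytokines(self) -> list[str]:
        return self.by_role("cytokine")


_LINEAGE = [
    "CD45", "CD3", "CD4", "CD8", "CD14", "CD19", "CD20", "CD27", "CD28",
    "CD161", "TCRVa7.2", "CD45RA", "CD45RO", "CCR7", "CCR4", "CCR6",
    "CXCR3", "CD25", "CD127", "CD56", "CD16", "CD38", "HLA-DR", "CD11c",
    "CD123", "ICOS", "CD57", "KLRG1", "IgD", "CD24",
]
_CHECKPOINT = ["PD1", "TIGIT"]
_CYTOKINE = ["IFNg", "TNFa", "IL17", "IL4"]


def default_panel() -> PanelManifest:
    """36-channel panel: 30 lineage + 2 checkpoint + 4 cytokine markers."""
    roles: dict[str, str] = {}
    roles.update({m: "lineage" for m in _LINEAGE})
    roles.update({m: "checkpoint" for m in _CHECKPOINT})
    roles.update({m: "cytokine" for m in _CYTOKINE})
    return PanelManifest(roles=roles)
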