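"""Canonical simulation scenarios mirroring the study conditions.

Each scenario returns the layout, panel and simulation keyword arguments for
one benchmark experiment, so scripts and tests run identical conditions:

* ``single_compartment``: 32 cells of a purely nuclear target (e.g. a nuclear
  envelope protein) -- the cross-contamination benchmark where every cell
  should report 100% nuclear localization.
* ``organelle_partial``: 103 cells of a mitochondria-targeted GFP-like
  target whose cytoplasmic fraction is clipped-normal (mean 0.79, sd 0.11) --
  partial solubilization of membranous organelles under short lysis.
* ``nfkb_timecourse``: stimulation sampled every 15 min over 0-120 min with
  the median nuclear fraction peaking at 60 min, 100 cells per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from sc2wb.layout import ArrayLayout
from sc2wb.simulate import TargetSpec, nfkb_pulse

__all__ = ["Scenario", "single_compartment", "organelle_partial", "nfkb_timecourse"]

#: stimulation sampling grid: 0-120 min at 15-min intervals
NFKB_TIMEPOINTS: tuple[int, ...] = tuple(range(0, 121, 15))


@dataclass(frozen=True)
class Scenario:
    layout: ArrayLayout
    panel: list[TargetSpec]
    n_cells: int
    sim_kwargs: dict = field(default_factory=dict)


def _grid_for(n_cells: int, n_cols: int = 8) -> ArrayLayout:
    n_rows = -(-n_cells // n_cols)
    return ArrayLayout(n_rows=n_rows, n_cols=n_cols)


def single_compartment(n_cells: int = 32, name: str = "laminAC") -> Scenario:
    """All band signal on the nuclear (west) side, band SNR >> 10."""
    target = TargetSpec(
        name=name,
        nuclear_fraction_mean=1.0,
        nuclear_fraction_sd=0.0,
        expected_compartment="nuclear",
    )
    return Scenario(layout=_grid_for(n_cells), panel=[target], n_cells=n_cells)


def organelle_partial(n_cells: int = 103, cytoplasmic_mean: float = 0.79,
                      sd: float = 0.11) -> Scenario:
    """Partially solubilized organelle target: cytoplasmic fraction 0.79 +/- 0.11."""
    target = TargetSpec(
        name="mtGFP",
        nuclear_fraction_mean=1.0 - cytoplasmic_mean,
        nuclear_fraction_sd=sd,
    )
    return Scenario(layout=_grid_for(n_cells), panel=[target], n_cells=n_cells)


def nfkb_timecourse(n_cells_per_timepoint: int = 100,
                    timepoints: Sequence[float] = NFKB_TIMEPOINTS) -> Scenario:
    """LPS-stimulation-like translocation transient peaking at 60 min."""
    target = TargetSpec(name="NFkB", nuclear_fraction_sd=0.11)
    sc = Scenario(
        layout=_grid_for(n_cells_per_timepoint, n_cols=10),
        panel=[target],
        n_cells=n_cells_per_timepoint,
        sim_kwargs={"timepoints": list(timepoints), "curve": nfkb_pulse()},
    )
    return sc
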