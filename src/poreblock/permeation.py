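"""K+ axial tracking and complete permeation-event counting.

An ion trace records, per frame, the axial position z relative to the pore
centre (z = 0 at the pore-centre plane, positive toward the selectivity
filter / extracellular side), the xy-radial distance to the pore axis, and a
coarse region label.  A complete permeation event is a traversal of the full
membrane span: the ion leaves z ≥ z_top (default +20 Å, the extracellular
membrane face) and reaches z ≤ z_bottom (default −20 Å) while staying within
the radial cutoff whenever it is between the two planes.  Hysteresis ensures
each traversal is counted once: after completing an event the ion must
re-cross the far threshold before a new event in the same direction can
begin, and an oscillation that never reaches the opposite plane counts
nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import CylinderSpec, cylinder_center
from .model import SelectionSet, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class IonTrace:
    """Per-frame axial/radial position and region label of one ion."""

    ion_id: int
    z: np.ndarray  # relative to the per-frame pore centre (Å)
    radial: np.ndarray  # xy distance to the pore axis (Å)
    region: np.ndarray  # "filter" | "pore" | "outside"
    times: np.ndarray  # ns

    def __post_init__(self) -> None:
        n = len(self.z)
        if not (len(self.radial) == len(self.region) == len(self.times) == n):
            raise ValueError("trace arrays must have equal length")


@dataclass
class PermeationEvent:
    """One complete traversal of the membrane span by one ion."""

    ion_id: int
    start_frame: int  # last frame on the entry side before the traversal
    end_frame: int  # first frame past the exit threshold
    direction: str  # "inward" (extracellular -> intracellular) | "outward"

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("start_frame must precede end_frame")


@dataclass
class PermeationResult:
    events: list[PermeationEvent]
    n_events: int
    n_ions_considered: int

    def to_json(self, path: str | Path) -> None:
        data = {
            "n_events": self.n_events,
            "n_ions_considered": self.n_ions_considered,
            "events": [asdict(e) for e in self.events],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)


def ion_axial_traces(
    traj: Trajectory, sel: SelectionSet, cyl: CylinderSpec | None = None
) -> list[IonTrace]:
    """Axial traces of all selected K+ ions, referenced to the pore centre.

    Region labels follow the cylinder geometry: ``filter`` for
    z > height/2, ``pore`` for |z| ≤ height/2 with radial ≤ radius,
    ``outside`` otherwise.
    """
    cyl = cyl or CylinderSpec()
    ions = np.asarray(sel.potassium_ions)
    if ions.size == 0:
        logger.warning("ion_axial_traces: empty ion selection")
        return []
    centers = np.stack(
        [cylinder_center(traj.coordinates[f], sel.pore_reference_ca) for f in range(traj.n_frames)]
    )
    radii = np.array(
        [
            cyl.effective_radius(traj.coordinates[f], sel.pore_reference_ca)
            for f in range(traj.n_frames)
        ]
    )
    traces = []
    for i, ion in enumerate(ions):
        rel = traj.coordinates[:, ion, :] - centers
        z = rel[:, 2]
        radial = np.hypot(rel[:, 0], rel[:, 1])
        region = np.where(
            z > cyl.height / 2.0,
            "filter",
            np.where((np.abs(z) <= cyl.height / 2.0) & (radial <= radii), "pore", "outside"),
        )
        traces.append(IonTrace(ion_id=i, z=z, radial=radial, region=region, times=traj.times))
    return traces


def count_permeation_events(
    traces: list[IonTrace],
    z_top: float = 20.0,
    z_bottom: float = -20.0,
    radial_cutoff: float = 10.0,
    initial_filter_only: bool = True,
) -> PermeationResult:
    """Count complete membrane traversals over a set of ion traces.

    State machine per ion: a frame at z ≥ z_top arms an inward attempt (the
    arming frame is refreshed while the ion stays above, so start_frame is the
    *last* frame above); reaching z ≤ z_bottom completes it, and symmetrically
    for outward.  Leaving the radial cutoff while strictly between the planes
    voids the current attempt — the ion must return to a threshold plane to
    re-arm.  With ``initial_filter_only`` (default) only ions whose first
    frame lies in the filter region contribute to the headline count,
    matching the convention of reporting the filter-resident ions; ions that
    end the trajectory mid-pore are in transit, not events.
    """
    if z_top <= z_bottom:
        raise ValueError(f"z_top ({z_top}) must exceed z_bottom ({z_bottom})")
    events: list[PermeationEvent] = []
    considered = 0
    for trace in traces:
        if initial_filter_only and trace.region[0] != "filter":
            continue
        considered += 1
        armed: str | None = None  # "above" | "below"
        start = -1
        for f, (z, r) in enumerate(zip(trace.z, trace.radial)):
            if z >= z_top:
                armed, start = "above", f
            elif z <= z_bottom:
                if armed == "above":
                    events.append(
                        PermeationEvent(
                            ion_id=trace.ion_id, start_frame=start, end_frame=f, direction="inward"
                        )
                    )
                armed, start = "below", f
            elif r > radial_cutoff:  # strictly between the planes, off axis
                armed = None
    # second pass for outward traversals (below -> above), kept separate so
    # the inward loop above stays readable
    for trace in traces:
        if initial_filter_only and trace.region[0] != "filter":
            continue
        armed = None
        start = -1
        for f, (z, r) in enumerate(zip(trace.z, trace.radial)):
            if z <= z_bottom:
                armed, start = "below", f
            elif z >= z_top:
                if armed == "below":
                    events.append(
                        PermeationEvent(
                            ion_id=trace.ion_id, start_frame=start, end_frame=f, direction="outward"
                        )
                    )
                armed, start = "above", f
            elif r > radial_cutoff:
                armed = None
    events.sort(key=lambda e: (e.end_frame, e.ion_id))
    return PermeationResult(events=events, n_events=len(events), n_ions_considered=considered)


def traces_to_csv(traces: list[IonTrace], path: str | Path) -> None:
    rows = []
    for t in traces:
        for f in range(len(t.z)):
            rows.append((t.ion_id, f, t.times[f], t.z[f], t.radial[f], t.region[f]))
    df = pd.DataFrame(rows, columns=["ion_id", "frame", "time_ns", "z", "radial", "region"])
    df.to_csv(path, index=False, float_format="%.6f")
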