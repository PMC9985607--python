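"""CSV dialects shared across the package.

Time-course tables are tidy: ``time_h, species, conc_M, replicate,
provenance`` (extra columns are tolerated and preserved on read).  Gel
lanes use ``species, mass_da, molar_amount, rel_intensity``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import RateParams, TimeCourse
from .synth import GelLane

TIMECOURSE_COLUMNS = ["time_h", "species", "conc_M", "replicate", "provenance"]


def write_timecourses(tcs, path) -> None:
    """Write one or many time courses to a tidy CSV."""
    if isinstance(tcs, TimeCourse):
        tcs = [tcs]
    frames = []
    for i, tc in enumerate(tcs):
        rep = tc.meta.get("replicate", i)
        frames.append(tc.to_frame(replicate=rep))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_timecourses(path, params: RateParams | None = None) -> list[TimeCourse]:
    """Read a tidy time-course CSV back into TimeCourse objects.

    One TimeCourse per replicate.  C0 is reconstructed as the total
    target-unit concentration at the first time point when the network is
    unknown, which is exact for runs started from pure monomer; readers
    needing exact conservation checks should re-simulate instead.
    """
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-course CSV missing columns: {sorted(missing)}")
    out = []
    for rep, grp in df.groupby("replicate"):
        wide = grp.pivot_table(index="species", columns="time_h",
                               values="conc_M", sort=False)
        wide = wide[sorted(wide.columns)]
        species = tuple(wide.index)
        conc = wide.to_numpy()
        times = np.asarray(wide.columns, dtype=float)
        c0 = _infer_c0(species, conc)
        tc = TimeCourse(times=times, species=species, conc=conc, c0=c0,
                        params=params or RateParams(),
                        provenance=str(grp["provenance"].iloc[0]))
        tc.meta["replicate"] = rep
        out.append(tc)
    return out


def _infer_c0(species, conc) -> float:
    total = 0.0
    for i, sp in enumerate(species):
        if sp[0] in "ATCL" and sp != "Ainact" and sp[1:].isdigit():
            total += int(sp[1:]) * conc[i, 0]
        elif sp in ("Ainact", "leakU"):
            total += conc[i, 0]
    return float(total)


def write_gel_lane(lane: GelLane, path) -> None:
    rel = lane.relative_intensities
    pd.DataFrame(
        [(b.species, b.mass_da, b.molar_amount, rel[b.species]) for b in lane.bands],
        columns=["species", "mass_da", "molar_amount", "rel_intensity"],
    ).to_csv(path, index=False)
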