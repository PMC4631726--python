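"""Bivariate flow-cytometry simulation and S-phase gate sorting.

Simulates the joint distribution of DNA content (DAPI fluorescence, in
C-value units) and EdU/A-488 intensity for nuclei released from three
root-tip zones, and the rectangular gating that sorts labeled nuclei
into early (E), middle (M) and late (L) S-phase windows:

* 0-1 mm (meristem): mitotic cycling — G1 at 2C, G2 at 4C, labeled S
  events spread between 2C and 4C.
* 1-3 mm: adds a substantial endocycling population — gap events at 4C
  and 8C plus labeled endo-S events between 4C and 8C.
* 3-5 mm (differentiated): little replication; mostly unlabeled 2C-8C
  events with a small labeled fraction.

Both axes carry multiplicative measurement noise (instrument CV).  The
published gate rectangles are graphical, so the numeric convention here
is declared, not extracted: the cycle's DNA interval (2->4 or 4->8 C) is
split into three equal-width windows sharing one EdU threshold placed
at a high quantile of the unlabeled population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GateWindow", "simulate_flow", "default_gates", "gate_sort", "ZONES"]

ZONES = ("0-1mm", "1-3mm", "3-5mm")

#: (fraction, phase, dna_law) mixtures per zone.  dna_law is either a
#: fixed C value (gap phases) or a (lo, hi) uniform interval (S phases).
_ZONE_MIX = {
    "0-1mm": [
        (0.40, "G1", 2.0),
        (0.25, "G2", 4.0),
        (0.35, "S", (2.0, 4.0)),
    ],
    "1-3mm": [
        (0.12, "G1", 2.0),
        (0.18, "S", (2.0, 4.0)),
        (0.30, "endo-G", 4.0),
        (0.28, "endo-S", (4.0, 8.0)),
        (0.12, "endo-G", 8.0),
    ],
    "3-5mm": [
        (0.30, "G1", 2.0),
        (0.40, "endo-G", 4.0),
        (0.25, "endo-G", 8.0),
        (0.03, "S", (2.0, 4.0)),
        (0.02, "endo-S", (4.0, 8.0)),
    ],
}

#: Instrument CVs on the two axes and EdU intensity law parameters.
DNA_CV = 0.04
EDU_UNLABELED_MEAN = 30.0
EDU_UNLABELED_SIGMA = 0.35  # lognormal sigma of autofluorescence
EDU_LABELED_MEAN = 500.0
EDU_LABELED_SIGMA = 0.45


@dataclass(frozen=True)
class GateWindow:
    """One rectangular sorting window in (DNA content, EdU) space."""

    label: str
    dna_lo: float
    dna_hi: float
    edu_min: float
    closed_hi: bool = False  # the last window includes its upper DNA edge

    def __post_init__(self) -> None:
        if self.label not in ("E", "M", "L"):
            raise ValueError(f"gate label must be E, M or L, got {self.label!r}")
        if not self.dna_lo < self.dna_hi:
            raise ValueError(f"gate needs dna_lo < dna_hi, got [{self.dna_lo}, {self.dna_hi})")

    def contains(self, dna: np.ndarray, edu: np.ndarray) -> np.ndarray:
        upper = dna <= self.dna_hi if self.closed_hi else dna < self.dna_hi
        return (dna >= self.dna_lo) & upper & (edu >= self.edu_min)


def simulate_flow(n: int, zone: str = "0-1mm", seed: int = 0) -> pd.DataFrame:
    """Simulate ``n`` flow events from one root zone.

    Returns a DataFrame with columns ``dna_content`` (measured, C
    units), ``edu_intensity`` (arbitrary fluorescence units),
    ``true_phase`` and ``true_progress`` (replication progress in [0, 1]
    for S events, NaN otherwise).  Deterministic for fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if zone not in _ZONE_MIX:
        raise ValueError(f"unknown zone {zone!r}; expected one of {ZONES}")
    rng = np.random.default_rng(seed)
    mix = _ZONE_MIX[zone]
    fracs = np.array([f for f, _, _ in mix])
    counts = rng.multinomial(n, fracs / fracs.sum())
    dna = np.empty(n)
    edu = np.empty(n)
    phase = np.empty(n, dtype=object)
    progress = np.full(n, np.nan)
    pos = 0
    for (frac, ph, law), k in zip(mix, counts):
        if k == 0:
            continue
        sl = slice(pos, pos + k)
        if isinstance(law, tuple):
            lo, hi = law
            u = rng.uniform(0.0, 1.0, size=k)
            dna[sl] = lo + u * (hi - lo)
            progress[sl] = u
            edu[sl] = EDU_LABELED_MEAN * rng.lognormal(0.0, EDU_LABELED_SIGMA, size=k)
        else:
            dna[sl] = law
            edu[sl] = EDU_UNLABELED_MEAN * rng.lognormal(0.0, EDU_UNLABELED_SIGMA, size=k)
        phase[sl] = ph
        pos += k
    dna_meas = dna * (1.0 + DNA_CV * rng.standard_normal(n))
    df = pd.DataFrame(
        {
            "dna_content": np.clip(dna_meas, 0.01, None),
            "edu_intensity": edu,
            "true_phase": phase,
            "true_progress": progress,
        }
    )
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def default_gates(cycle: str, events: pd.DataFrame, edu_quantile: float = 0.995) -> list[GateWindow]:
    """Equal-thirds E/M/L gates for one cycle with a quantile EdU threshold.

    The DNA interval between the cycle endpoints (2C->4C mitotic,
    4C->8C endocycle) is split into three equal-width windows; the
    shared EdU threshold is the ``edu_quantile`` of the simulated
    unlabeled (non-S) events, excluding >=99% of them by construction.
    """
    if cycle == "mitotic":
        lo, hi = 2.0, 4.0
    elif cycle == "endocycle":
        lo, hi = 4.0, 8.0
    else:
        raise ValueError(f"unknown cycle {cycle!r}")
    unlabeled = events[~events["true_phase"].isin(("S", "endo-S"))]
    if unlabeled.empty:
        edu_min = 0.0
    else:
        edu_min = float(unlabeled["edu_intensity"].quantile(edu_quantile))
    labeled_phase = "S" if cycle == "mitotic" else "endo-S"
    labeled = events[(events["true_phase"] == labeled_phase) & (events["edu_intensity"] >= edu_min)]
    if labeled.empty:
        raise ValueError(f"no labeled {labeled_phase} events above the EdU threshold")
    thirds = np.linspace(lo, hi, 4)
    return [
        GateWindow("E", thirds[0], thirds[1], edu_min),
        GateWindow("M", thirds[1], thirds[2], edu_min),
        GateWindow("L", thirds[2], thirds[3], edu_min, closed_hi=True),
    ]


def gate_sort(events: pd.DataFrame, gates: list[GateWindow]) -> dict[str, pd.DataFrame]:
    """Partition events into the E/M/L windows plus the ungated remainder.

    Gates must be pairwise disjoint in (DNA, EdU) space; every event
    lands in exactly one subset.
    """
    for i, g in enumerate(gates):
        for h in gates[i + 1 :]:
            dna_overlap = g.dna_lo < h.dna_hi and h.dna_lo < g.dna_hi
            edge_touch = (g.closed_hi and g.dna_hi == h.dna_lo) or (h.closed_hi and h.dna_hi == g.dna_lo)
            if dna_overlap or edge_touch:
                raise ValueError(f"gates {g.label} and {h.label} overlap in DNA range")
    dna = events["dna_content"].to_numpy()
    edu = events["edu_intensity"].to_numpy()
    assigned = np.full(len(events), "ungated", dtype=object)
    for g in gates:
        hit = g.contains(dna, edu)
        assigned[hit] = g.label
    out = {g.label: events[assigned == g.label] for g in gates}
    out["ungated"] = events[assigned == "ungated"]
    return out
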