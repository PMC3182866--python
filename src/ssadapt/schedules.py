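"""Trial schedules for the five object-rotation experiments (plus the
compliance-calibration experiment).

Each schedule is an ordered list of trials.  A trial has one of three
modes:

* ``exposure`` — full object dynamics; handle displacement reflects the
  error in the subject's mass estimate.
* ``zero_force`` — object forces off; any anticipatory force displaces the
  handle (drives de-adaptation).
* ``error_clamp`` — the handle is clamped; anticipatory forces are
  measured without driving learning.

Within a block, trials strictly alternate clockwise / counter-clockwise
40-degree rotations.  Wherever a protocol says "random" (clamp positions,
orientation or mass orders) the placement is drawn from a seeded generator,
so a schedule is a pure function of (experiment, group, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4", "exp5", "expS1")
MODES = ("exposure", "zero_force", "error_clamp")

#: Orientation grid spacing (degrees) of the context representation.
GRID_STEP_DEG = 22.5

#: The five calibrated / trained orientations used across experiments.
FIVE_ORIENTATIONS = (0.0, -45.0, -90.0, -135.0, 180.0)

DEFAULT_MASS_FRAC = 0.01
EXP3_MASSES = (0.007, 0.010, 0.013)

EXP2_PROBES = {
    1: (0.0, -22.5, -45.0, -90.0, 180.0),
    2: (180.0, -157.5, -135.0, -90.0, 0.0),
}
EXP2_TRAINING = {1: 0.0, 2: 180.0}


def wrap_deg(angle: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = float((angle + 180.0) % 360.0 - 180.0)
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class Trial:
    index: int
    mode: str
    orientation_deg: float
    direction: str  # "CW" | "CCW"
    mass_frac_bm: float
    phase_label: str
    block_id: int
    familiarization: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.direction not in ("CW", "CCW"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.mass_frac_bm <= 0:
            raise ValueError("mass_frac_bm must be positive")
        if abs(self.orientation_deg / GRID_STEP_DEG - round(self.orientation_deg / GRID_STEP_DEG)) > 1e-9:
            raise ValueError(f"orientation {self.orientation_deg} is off the 22.5-degree grid")


@dataclass(frozen=True)
class Schedule:
    experiment_id: str
    trials: tuple[Trial, ...]
    seed: int
    group: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def main_trials(self) -> tuple[Trial, ...]:
        """Trials excluding any familiarization block."""
        return tuple(t for t in self.trials if not t.familiarization)

    def modes(self) -> np.ndarray:
        return np.array([t.mode for t in self.trials])

    def orientations(self) -> np.ndarray:
        return np.array([t.orientation_deg for t in self.trials])

    def masses(self) -> np.ndarray:
        return np.array([t.mass_frac_bm for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "index": t.index,
                    "mode": t.mode,
                    "orientation_deg": t.orientation_deg,
                    "direction": t.direction,
                    "mass_frac_bm": t.mass_frac_bm,
                    "phase_label": t.phase_label,
                    "block_id": t.block_id,
                    "familiarization": t.familiarization,
                }
                for t in self.trials
            ]
        )

    def to_json(self) -> str:
        payload = {
            "experiment_id": self.experiment_id,
            "group": self.group,
            "seed": self.seed,
            "trials": [asdict(t) for t in self.trials],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Schedule":
        payload = json.loads(text)
        trials = tuple(Trial(**t) for t in payload["trials"])
        return cls(
            experiment_id=payload["experiment_id"],
            trials=trials,
            seed=payload["seed"],
            group=payload.get("group"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Schedule":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Builder:
    """Accumulates trials with strict CW/CCW alternation per block."""

    def __init__(self) -> None:
        self.trials: list[Trial] = []
        self._dir_state: dict[int, int] = {}

    def add(
        self,
        mode: str,
        orientation: float,
        phase: str,
        block: int,
        mass: float = DEFAULT_MASS_FRAC,
        familiarization: bool = False,
    ) -> None:
        k = self._dir_state.get(block, 0)
        self._dir_state[block] = k + 1
        self.trials.append(
            Trial(
                index=len(self.trials),
                mode=mode,
                orientation_deg=wrap_deg(orientation),
                direction="CW" if k % 2 == 0 else "CCW",
                mass_frac_bm=mass,
                phase_label=phase,
                block_id=block,
                familiarization=familiarization,
            )
        )

    def done(self, experiment_id: str, seed: int, group: int | None = None) -> Schedule:
        return Schedule(experiment_id=experiment_id, trials=tuple(self.trials), seed=seed, group=group)


def _exp1(seed: int) -> Schedule:
    """Single-context adaptation / de-adaptation.

    48 familiarization zero-force trials, then the 320-trial main
    experiment: 48 zero-force (pre), 224 exposure (one error clamp per
    8-trial bin in the final 128 exposure trials, balanced 8 CW / 8 CCW),
    48 zero-force (post).
    """
    rng = np.random.default_rng(seed)
    b = _Builder()
    for _ in range(48):
        b.add("zero_force", 0.0, "familiarization", 0, familiarization=True)
    for _ in range(48):
        b.add("zero_force", 0.0, "pre", 1)
    # exposure block: positions 0..223 within the block; bins of 8 from 96.
    clamp_pos: set[int] = set()
    for bin_i in range(16):
        start = 96 + 8 * bin_i
        # alternate CW/CCW bins; within-block direction is CW at even offsets
        offsets = (0, 2, 4, 6) if bin_i % 2 == 0 else (1, 3, 5, 7)
        clamp_pos.add(start + int(rng.choice(offsets)))
    for j in range(224):
        mode = "error_clamp" if j in clamp_pos else "exposure"
        b.add(mode, 0.0, "exposure", 2)
    for _ in range(48):
        b.add("zero_force", 0.0, "post", 3)
    return b.done("exp1", seed)


def _exp2(seed: int, group: int) -> Schedule:
    """Multiple-context de-adaptation.

    64 initial exposure trials at the training orientation, then 15
    blocks of 30 trials: 2 error clamps (training), 8 zero-force trials
    at a probe orientation, 2 error clamps (training), 18 re-exposure
    trials (training).  Probes appear once per cycle in a seeded
    permutation, 3 cycles.
    """
    if group not in (1, 2):
        raise ValueError("exp2 requires group 1 or 2")
    rng = np.random.default_rng(seed)
    training = EXP2_TRAINING[group]
    probes = EXP2_PROBES[group]
    order: list[float] = []
    for _ in range(3):
        order.extend(np.array(probes)[rng.permutation(5)])
    b = _Builder()
    for _ in range(64):
        b.add("exposure", training, "initial_exposure", 0)
    for blk, probe in enumerate(order, start=1):
        for _ in range(2):
            b.add("error_clamp", training, f"block{blk:02d}_clamp_pre", blk)
        for _ in range(8):
            b.add("zero_force", probe, f"block{blk:02d}_deadapt", blk)
        for _ in range(2):
            b.add("error_clamp", training, f"block{blk:02d}_clamp_post", blk)
        for _ in range(18):
            b.add("exposure", training, f"block{blk:02d}_reexposure", blk)
    return b.done("exp2", seed, group=group)


def _exp3(seed: int, masses: Sequence[float] = EXP3_MASSES) -> Schedule:
    """Adaptation to three object masses.

    Three 90-trial mass blocks in seeded pseudo-random order: 60 exposure
    trials at 0 degrees, then 30 trials with one error clamp per 5-trial
    bin (3 clamps at 0 degrees, 3 at -90 degrees, assignment seeded).
    """
    if masses is None:
        masses = EXP3_MASSES
    if len(masses) < 2:
        raise ValueError("exp3 requires at least 2 masses")
    rng = np.random.default_rng(seed)
    mass_order = np.array(masses)[rng.permutation(len(masses))]
    b = _Builder()
    for mi, mass in enumerate(mass_order):
        for _ in range(60):
            b.add("exposure", 0.0, f"mass{mi}_exposure", mi, mass=float(mass))
        # 6 bins of 5; which bins probe the transfer orientation is seeded
        transfer_bins = set(rng.choice(6, size=3, replace=False).tolist())
        clamp_at = {bin_i: int(rng.integers(0, 5)) for bin_i in range(6)}
        for j in range(30):
            bin_i, off = divmod(j, 5)
            if off == clamp_at[bin_i]:
                theta = -90.0 if bin_i in transfer_bins else 0.0
                b.add("error_clamp", theta, f"mass{mi}_probe", mi, mass=float(mass))
            else:
                b.add("exposure", 0.0, f"mass{mi}_probe", mi, mass=float(mass))
    return b.done("exp3", seed)


def _exp4(seed: int) -> Schedule:
    """Dual-context adaptation: 11 cycles of paired 24-trial blocks at
    180 and 0 degrees.  First and last cycles are zero-force; each
    exposure block carries 4 seeded error clamps, never block-initial."""
    rng = np.random.default_rng(seed)
    b = _Builder()
    block = 0
    for cycle in range(11):
        for theta in (180.0, 0.0):
            if cycle in (0, 10):
                phase = "pre" if cycle == 0 else "post"
                for _ in range(24):
                    b.add("zero_force", theta, phase, block)
            else:
                clamp_pos = set(rng.choice(np.arange(1, 24), size=4, replace=False).tolist())
                for j in range(24):
                    mode = "error_clamp" if j in clamp_pos else "exposure"
                    b.add(mode, theta, "exposure", block)
            block += 1
    return b.done("exp4", seed)


def _exp5(seed: int) -> Schedule:
    """Multiple-context adaptation over the five orientations.

    2 pre cycles (5 blocks x 4 error clamps), 5 exposure cycles
    (5 blocks x [2 clamps, 16 exposure, 2 clamps]), 2 post cycles;
    orientation order permuted per cycle.
    """
    rng = np.random.default_rng(seed)
    oris = np.array(FIVE_ORIENTATIONS)
    b = _Builder()
    block = 0
    last_theta: float | None = None

    def next_cycle() -> np.ndarray:
        # every block changes orientation relative to its predecessor, so
        # redraw if a cycle would open with the previous cycle's closer
        nonlocal last_theta
        while True:
            order = oris[rng.permutation(5)]
            if last_theta is None or order[0] != last_theta:
                last_theta = float(order[-1])
                return order

    def clamp_cycle(phase: str) -> None:
        nonlocal block
        for theta in next_cycle():
            for _ in range(4):
                b.add("error_clamp", float(theta), phase, block)
            block += 1

    for _ in range(2):
        clamp_cycle("pre")
    for _ in range(5):
        for theta in next_cycle():
            for _ in range(2):
                b.add("error_clamp", float(theta), "exposure", block)
            for _ in range(16):
                b.add("exposure", float(theta), "exposure", block)
            for _ in range(2):
                b.add("error_clamp", float(theta), "exposure", block)
            block += 1
    for _ in range(2):
        clamp_cycle("post")
    return b.done("exp5", seed)


def _expS1(seed: int, n_cycles: int = 3, n_adapt: int = 30, n_deadapt: int = 20) -> Schedule:
    """Compliance calibration: repeated adapt / de-adapt cycles at each of
    the five orientations (order permuted per cycle)."""
    rng = np.random.default_rng(seed)
    oris = np.array(FIVE_ORIENTATIONS)
    b = _Builder()
    block = 0
    for cycle in range(n_cycles):
        for theta in oris[rng.permutation(5)]:
            for _ in range(n_adapt):
                b.add("exposure", float(theta), f"cycle{cycle}_adapt", block)
            for _ in range(n_deadapt):
                b.add("zero_force", float(theta), f"cycle{cycle}_deadapt", block)
            block += 1
    return b.done("expS1", seed)


def build_schedule(
    experiment_id: str,
    seed: int = 0,
    group: int | None = None,
    masses: Sequence[float] | None = None,
    n_cycles: int = 3,
) -> Schedule:
    """Construct the trial sequence for one experiment.

    Parameters
    ----------
    experiment_id : one of exp1..exp5, expS1
    seed : seeds every "random"/"pseudo-random" placement in the protocol
    group : required for exp2 (1 trains at 0 deg, 2 at 180 deg)
    masses : exp3 mass fractions of body mass (default 0.7/1.0/1.3 %)
    n_cycles : number of adapt/de-adapt cycles for expS1
    """
    if experiment_id == "exp1":
        return _exp1(seed)
    if experiment_id == "exp2":
        if group is None:
            raise ValueError("exp2 requires group=1 or group=2")
        return _exp2(seed, group)
    if experiment_id == "exp3":
        return _exp3(seed, EXP3_MASSES if masses is None else masses)
    if experiment_id == "exp4":
        return _exp4(seed)
    if experiment_id == "exp5":
        return _exp5(seed)
    if experiment_id == "expS1":
        return _expS1(seed, n_cycles=n_cycles)
    raise ValueError(f"unknown experiment_id {experiment_id!r}")
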