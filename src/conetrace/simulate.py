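"""Agent-based simulator of a 5-mosquito WHO cone assay.

Each mosquito is a state-machine agent with four behavioural states —
contacting the net (N), flying within the cone (F), resting on the cone
surface (C) and knocked down (K) — advanced on a fixed 0.1-s grid.
Continuous transition hazards are discretised per step as
``p = 1 - exp(-rate * dt)``; competing exits from the flying state are
resolved proportionally to their rates.  Irritancy (excito-repellency)
enters as a multiplier ``1 + irritancy_gain * cumulative_contact_time`` on
the activation rates N→F and C→F, so activity ramps up as agents accumulate
exposure to the treated net.  Knockdown is an absorbing state whose hazard
grows with cumulative net-contact time, ``toxicity_hazard * contact_time``,
producing the delayed knockdown accumulation seen in real assays.

The simulator's output (:class:`TruthLog`) doubles as the ground-truth
oracle for the vision stage: it records every agent's state and pixel
position at every frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import ConeGeometry

# integer state codes used internally; letters at the API surface
STATE_N, STATE_F, STATE_C, STATE_K = 0, 1, 2, 3
STATE_LETTERS = np.array(["N", "F", "C", "K"])
_LETTER_TO_CODE = {s: i for i, s in enumerate(STATE_LETTERS)}

_WALL_MARGIN = 2.0  # px kept between flying agents and the cone wall
_TURN_SD = 0.9  # rad per step; correlated-random-walk turning noise


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioural transition hazards and exposure response of one cohort.

    Rates are per-second hazards on the N/F/C state graph; ``irritancy_gain``
    (1/s of contact) scales the activation rates with accumulated contact
    time, and ``toxicity_hazard`` (1/s per second of contact) drives the
    absorbing knockdown transition.  ``flight_speed`` is in px/s.
    """

    rate_C_to_F: float = 0.05
    rate_F_to_C: float = 0.25
    rate_F_to_N: float = 0.15
    rate_N_to_F: float = 0.08
    irritancy_gain: float = 0.0
    toxicity_hazard: float = 0.0
    flight_speed: float = 120.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rate_C_to_F",
            "rate_F_to_C",
            "rate_F_to_N",
            "rate_N_to_F",
            "irritancy_gain",
            "toxicity_hazard",
            "flight_speed",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def with_seed(self, seed: int) -> "BehaviorParams":
        return replace(self, rng_seed=int(seed))


@dataclass(frozen=True)
class TruthLog:
    """Ground-truth per-frame record of every simulated agent.

    ``states`` is ``(n_frames, n_agents)`` int8 (codes N=0 F=1 C=2 K=3),
    ``positions`` is ``(n_frames, n_agents, 2)`` float ``(x, y)`` pixels and
    ``contact_time`` the cumulative seconds spent contacting the net.
    """

    states: np.ndarray
    positions: np.ndarray
    contact_time: np.ndarray
    dt: float

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_agents(self) -> int:
        return self.states.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt

    def state_counts(self) -> np.ndarray:
        """Per-frame counts of each state, shape ``(n_frames, 4)``."""
        out = np.zeros((self.n_frames, 4), dtype=int)
        for code in range(4):
            out[:, code] = (self.states == code).sum(axis=1)
        return out

    def moving_mask(self) -> np.ndarray:
        """Agents in flight (the only state with per-frame displacement)."""
        return self.states == STATE_F

    def to_dataframe(self) -> pd.DataFrame:
        t, n = self.n_frames, self.n_agents
        frame = np.repeat(np.arange(t), n)
        agent = np.tile(np.arange(n), t)
        return pd.DataFrame(
            {
                "frame_index": frame,
                "time_s": frame * self.dt,
                "agent_id": agent,
                "state": STATE_LETTERS[self.states.ravel()],
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "cumulative_contact_s": self.contact_time.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float | None = None) -> "TruthLog":
        frames = np.sort(df["frame_index"].unique())
        agents = np.sort(df["agent_id"].unique())
        t, n = len(frames), len(agents)
        if dt is None:
            times = np.sort(df["time_s"].unique())
            dt = float(times[1] - times[0]) if t > 1 else 0.1
        df = df.sort_values(["frame_index", "agent_id"])
        states = df["state"].map(_LETTER_TO_CODE).to_numpy().reshape(t, n).astype(np.int8)
        pos = df[["x", "y"]].to_numpy().reshape(t, n, 2)
        contact = df["cumulative_contact_s"].to_numpy().reshape(t, n)
        return cls(states=states, positions=pos, contact_time=contact, dt=dt)

    @classmethod
    def read_csv(cls, path) -> "TruthLog":
        return cls.from_dataframe(pd.read_csv(path))


def _initial_positions(
    rng: np.random.Generator, geometry: ConeGeometry, n: int
) -> np.ndarray:
    """Uniform rejection sampling inside the cone interior."""
    out = np.empty((n, 2))
    filled = 0
    lo = np.array([0.0, geometry.apex_y])
    hi = np.array([geometry.frame_width, geometry.base_y])
    while filled < n:
        cand = rng.uniform(lo, hi, size=(4 * n, 2))
        ok = geometry.contains(cand, margin=_WALL_MARGIN)
        take = cand[ok][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def simulate_cohort(
    params: BehaviorParams,
    geometry: ConeGeometry | None = None,
    n_agents: int = 5,
    duration: float = 180.0,
    dt: float = 0.1,
    initial_state: str = "F",
) -> TruthLog:
    """Simulate one cone assay and return the ground-truth log.

    The log has ``duration/dt + 1`` time points (t = 0 inclusive through
    t = duration inclusive).  Agents start flying (``initial_state="F"``,
    the default: mosquitoes are introduced flying) at uniform positions in
    the cone interior; other initial states are available for degenerate
    scenarios.  Knockdown is checked first each step with hazard
    ``toxicity_hazard * cumulative_contact_time``; knocked-down agents drop
    to the net edge and stay static.
    """
    if geometry is None:
        geometry = ConeGeometry.default()
    if initial_state not in ("N", "F", "C"):
        raise ValueError("initial_state must be one of N, F, C")
    n_steps_f = duration / dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9 or n_steps < 1:
        raise ValueError(f"dt={dt} must divide duration={duration}")

    rng = np.random.default_rng(params.rng_seed)
    n_frames = n_steps + 1

    states = np.empty((n_frames, n_agents), dtype=np.int8)
    positions = np.empty((n_frames, n_agents, 2))
    contact = np.zeros((n_frames, n_agents))

    state = np.full(n_agents, _LETTER_TO_CODE[initial_state], dtype=np.int8)
    pos = _initial_positions(rng, geometry, n_agents)
    if initial_state == "N":
        lo, hi = geometry.net_x_range
        pos[:, 0] = np.clip(pos[:, 0], lo + _WALL_MARGIN, hi - _WALL_MARGIN)
        pos[:, 1] = geometry.base_y - 0.5
    heading = rng.uniform(0.0, 2.0 * np.pi, size=n_agents)
    cum_contact = np.zeros(n_agents)

    states[0] = state
    positions[0] = pos
    contact[0] = cum_contact

    net_lo, net_hi = geometry.net_x_range
    net_y = geometry.base_y - 0.5
    step_len = params.flight_speed * dt

    for t in range(1, n_frames):
        # contact time accrues while in state N at the start of the step
        in_contact = state == STATE_N
        cum_contact = cum_contact + in_contact * dt

        new_state = state.copy()
        u_kd = rng.uniform(size=n_agents)
        u_leave = rng.uniform(size=n_agents)
        u_dest = rng.uniform(size=n_agents)
        turn = rng.normal(0.0, _TURN_SD, size=n_agents)

        alive = state != STATE_K
        # knockdown: absorbing, hazard proportional to cumulative contact
        p_kd = -np.expm1(-params.toxicity_hazard * cum_contact * dt)
        knocked = alive & (u_kd < p_kd)
        new_state[knocked] = STATE_K

        gain = 1.0 + params.irritancy_gain * cum_contact

        # F -> {C, N}: competing exits split proportionally to their rates
        is_f = alive & ~knocked & (state == STATE_F)
        rate_out = params.rate_F_to_C + params.rate_F_to_N
        if rate_out > 0:
            p_leave = -math.expm1(-rate_out * dt)
            leave = is_f & (u_leave < p_leave)
            to_c = leave & (u_dest < params.rate_F_to_C / rate_out)
            new_state[to_c] = STATE_C
            new_state[leave & ~to_c] = STATE_N

        # C -> F and N -> F, irritancy-scaled
        is_c = alive & ~knocked & (state == STATE_C)
        is_n = alive & ~knocked & (state == STATE_N)
        p_cf = -np.expm1(-params.rate_C_to_F * gain * dt)
        p_nf = -np.expm1(-params.rate_N_to_F * gain * dt)
        new_state[is_c & (u_leave < p_cf)] = STATE_F
        new_state[is_n & (u_leave < p_nf)] = STATE_F

        # movement
        landed_n = (new_state == STATE_N) & (state != STATE_N)
        dropped = (new_state == STATE_K) & (state != STATE_K)
        flying = new_state == STATE_F

        if np.any(flying):
            idx = np.flatnonzero(flying)
            heading[idx] = heading[idx] + turn[idx]
            prop = pos[idx] + step_len * np.column_stack(
                [np.cos(heading[idx]), np.sin(heading[idx])]
            )
            ok = geometry.contains(prop, margin=_WALL_MARGIN)
            for j, agent in enumerate(idx):
                if ok[j]:
                    pos[agent] = prop[j]
                    continue
                # wall hit: retry with random headings, else stay put
                for _ in range(8):
                    h = rng.uniform(0.0, 2.0 * np.pi)
                    cand = pos[agent] + step_len * np.array([math.cos(h), math.sin(h)])
                    if geometry.contains(cand, margin=_WALL_MARGIN):
                        pos[agent] = cand
                        heading[agent] = h
                        break

        if np.any(landed_n):
            idx = np.flatnonzero(landed_n)
            pos[idx, 0] = np.clip(pos[idx, 0], net_lo + _WALL_MARGIN, net_hi - _WALL_MARGIN)
            pos[idx, 1] = net_y
        if np.any(dropped):
            idx = np.flatnonzero(dropped)
            pos[idx, 0] = np.clip(pos[idx, 0], net_lo + _WALL_MARGIN, net_hi - _WALL_MARGIN)
            pos[idx, 1] = net_y

        state = new_state
        states[t] = state
        positions[t] = pos
        contact[t] = cum_contact

    return TruthLog(states=states, positions=positions, contact_time=contact, dt=dt)


def render_video(
    truth: TruthLog,
    geometry: ConeGeometry | None = None,
    blob_radius: float = 3.0,
    agent_intensity: float = 200.0,
    noise_sd: float = 4.0,
    seed: int = 0,
    background_cone: float = 70.0,
    background_outside: float = 30.0,
) -> np.ndarray:
    """Render a grayscale frame stream (T, H, W uint8) from a truth log.

    Static background (cone silhouette shading) plus one disk per agent at
    its truth position plus i.i.d. Gaussian pixel noise clipped to [0, 255].
    Overlapping agents merge into a single blob (occlusion is deliberate).
    """
    if geometry is None:
        geometry = ConeGeometry.default()
    if blob_radius < 1:
        raise ValueError("blob_radius must be >= 1")
    h, w = geometry.frame_height, geometry.frame_width

    background = np.full((h, w), background_outside, dtype=np.float32)
    background[geometry.mask()] = background_cone

    r = int(math.ceil(blob_radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (dx * dx + dy * dy) <= blob_radius * blob_radius

    rng = np.random.default_rng(seed)
    frames = np.empty((truth.n_frames, h, w), dtype=np.uint8)
    for t in range(truth.n_frames):
        img = background.copy()
        for a in range(truth.n_agents):
            cx = int(round(truth.positions[t, a, 0]))
            cy = int(round(truth.positions[t, a, 1]))
            y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
            x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
            if y0 >= y1 or x0 >= x1:
                continue
            sub = disk[y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)]
            patch = img[y0:y1, x0:x1]
            patch[sub] = np.maximum(patch[sub], agent_intensity)
        if noise_sd > 0:
            img = img + noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
        np.clip(img, 0.0, 255.0, out=img)
        frames[t] = img.astype(np.uint8)
    return frames
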