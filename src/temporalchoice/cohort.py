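"""Synthetic two-group (rTPJ vs. vertex) x two-session (pre/post) cohorts.

Generates the full study structure the analysis modules expect: the fully
crossed 9 reward x 9 delay intertemporal design (81 combinations, repeated
twice per session, 81 trials per run), the 2x2x2 mental time-travel design
with 9 events per cell (72 per session, 36 per run), participant-level
discount parameters, softmax choices, and log-normal response times with a
configurable three-way group x session x event-time effect.

All randomness flows from a single master seed through named substreams, so
regenerating a cohort with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .discount import (
    CHOICE_TABLE_COLUMNS,
    SS_AMOUNT,
    DiscountParams,
    choice_prob,
    subjective_value,
)

__all__ = [
    "REWARD_GRID",
    "DELAY_GRID",
    "RtEffects",
    "CohortConfig",
    "substream",
    "make_choice_design",
    "make_timetravel_design",
    "sample_participant_params",
    "simulate_choices",
    "simulate_timetravel_rts",
    "simulate_cohort",
    "write_cohort",
]

#: LL reward levels in CHF (the SS option is fixed at 10 CHF today).
REWARD_GRID = (10, 11, 12, 13, 14, 15, 16, 18, 20)

#: Delays in days.
DELAY_GRID = (1, 5, 10, 20, 40, 60, 90, 120, 180)

RT_TABLE_COLUMNS = [
    "participant_id",
    "group",
    "session",
    "run",
    "event_type",
    "perspective",
    "event_time",
    "rt",
    "log_rt",
]

#: Response window in seconds; RTs are truncated to (0, RESPONSE_WINDOW].
RESPONSE_WINDOW = 3.0


@dataclass(frozen=True)
class RtEffects:
    """Coefficients of the log-RT generator (natural-log seconds).

    ``log_rt = intercept + participant intercept + perspective_future * 1[future
    perspective] + event_type_nonpersonal * 1[nonpersonal] + event_time_future *
    1[relative-future event] + session_x_event_time * 1[post] * 1[future event]
    + group_x_session_x_event_time * 1[rTPJ] * 1[post] * 1[future event] +
    noise``.  With this indicator coding the between-group difference in
    (post minus pre) future-minus-past contrasts equals
    ``group_x_session_x_event_time`` exactly.
    """

    intercept: float = 0.0  # log(1 s)
    participant_sd: float = 0.10
    perspective_future: float = 0.04
    event_type_nonpersonal: float = 0.035
    event_time_future: float = 0.05
    session_x_event_time: float = -0.032
    group_x_session_x_event_time: float = 0.045
    noise_sd: float = 0.20


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort.

    ``param_population`` maps parameter name -> (location, scale) of a
    log-normal on the natural-log scale.  ``ctbs_effect_s`` multiplies the
    post-session ``s`` of rTPJ-group participants only (1.0 = null).
    ``susceptibility_sd`` adds a shared participant-level latent factor that
    scales both the stimulation effect on ``s`` and the RT three-way effect,
    inducing a positive cross-task correlation when non-zero.
    """

    n_per_group: int = 30
    reward_grid: tuple = REWARD_GRID
    delay_grid: tuple = DELAY_GRID
    repeats_per_session: int = 2
    events_per_cell: int = 9
    param_population: dict = field(default_factory=lambda: {
        "k": (float(np.log(0.01)), 0.5),
        "s": (0.0, 0.3),
        "beta_temp": (0.0, 0.5),
    })
    ctbs_effect_s: float = 1.0
    session_noise_sd: float = 0.0
    susceptibility_sd: float = 0.0
    rt_effects: RtEffects = field(default_factory=RtEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.reward_grid or not self.delay_grid:
            raise ValueError("grids must be non-empty")
        if isinstance(self.rt_effects, dict):
            self.rt_effects = RtEffects(**self.rt_effects)
        for name, (_, scale) in self.param_population.items():
            if scale < 0:
                raise ValueError(f"param_population[{name!r}] scale must be >= 0")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["reward_grid"] = list(self.reward_grid)
        out["delay_grid"] = list(self.delay_grid)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        data = dict(data)
        for key in ("reward_grid", "delay_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Named, order-independent child RNG derived from the master seed.

    String keys are hashed with CRC-32 so the stream depends only on the
    (seed, keys) pair, not on how many other streams were drawn before it.
    """
    ints = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([master_seed, *ints]))


def make_choice_design(
    reward_grid=REWARD_GRID,
    delay_grid=DELAY_GRID,
    repeats: int = 2,
    rng: np.random.Generator | None = None,
    n_runs: int = 2,
) -> pd.DataFrame:
    """Full cross of reward and delay grids, each combination ``repeats`` times.

    Order is randomized when ``rng`` is given; trials are split evenly over
    ``n_runs`` runs in presentation order.  Default grids give 81 unique
    combinations and 162 trials per session over 2 runs.
    """
    if not len(reward_grid) or not len(delay_grid):
        raise ValueError("grids must be non-empty")
    combos = list(product(reward_grid, delay_grid)) * repeats
    df = pd.DataFrame(combos, columns=["reward_ll", "delay"])
    if rng is not None:
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["run"] = 1 + (np.arange(len(df)) * n_runs) // len(df)
    return df


def make_timetravel_design(
    events_per_cell: int = 9,
    rng: np.random.Generator | None = None,
    n_runs: int = 2,
) -> pd.DataFrame:
    """2x2x2 factorial time-travel design with ``events_per_cell`` per cell.

    Factors: event_type (personal/nonpersonal), perspective (now/future),
    event_time (past/future).  Defaults give 72 trials per session, split 36
    per run over 2 runs.
    """
    if events_per_cell < 1:
        raise ValueError("events_per_cell must be >= 1")
    cells = list(product(
        ("personal", "nonpersonal"),
        ("now", "future"),
        ("past", "future"),
    ))
    rows = [cell for cell in cells for _ in range(events_per_cell)]
    df = pd.DataFrame(rows, columns=["event_type", "perspective", "event_time"])
    if rng is not None:
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["run"] = 1 + (np.arange(len(df)) * n_runs) // len(df)
    return df


def _participant_ids(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for g_idx, group in enumerate(("rTPJ", "vertex")):
        for i in range(config.n_per_group):
            rows.append({"participant_id": f"{group[0]}{i + 1:03d}", "group": group})
    return pd.DataFrame(rows)


def sample_participant_params(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-participant, per-session generalized hyperbolic parameters.

    ``k``, ``s`` and ``beta_temp`` are log-normal.  Post-session parameters
    equal pre-session ones up to optional log-normal session noise, except
    that ``s`` of rTPJ participants is additionally multiplied by
    ``ctbs_effect_s`` (scaled by the participant's latent susceptibility when
    ``susceptibility_sd > 0``).  Returns a long table with one row per
    participant and session plus the latent susceptibility ``u``.
    """
    rows = []
    for _, row in _participant_ids(config).iterrows():
        pid, group = row["participant_id"], row["group"]
        r = rng if rng is not None else substream(config.seed, "params", pid)
        pre = {
            name: float(np.exp(loc + scale * r.standard_normal()))
            for name, (loc, scale) in config.param_population.items()
        }
        u = float(r.standard_normal())
        post = dict(pre)
        if config.session_noise_sd > 0:
            for name in post:
                post[name] = float(
                    post[name] * np.exp(config.session_noise_sd * r.standard_normal())
                )
        if group == "rTPJ" and "s" in post:
            log_shift = np.log(config.ctbs_effect_s) + config.susceptibility_sd * u
            post["s"] = float(post["s"] * np.exp(log_shift))
        for session, params in (("pre", pre), ("post", post)):
            rows.append({"participant_id": pid, "group": group, "session": session,
                         "u": u, **params})
    return pd.DataFrame(rows)


def simulate_choices(
    params: DiscountParams,
    design: pd.DataFrame,
    rng: np.random.Generator,
    participant_id: str = "p001",
    group: str = "rTPJ",
    session: str = "pre",
) -> pd.DataFrame:
    """Draw Bernoulli choices for each design trial under ``params``."""
    sv = subjective_value(params, design["reward_ll"].to_numpy(),
                          design["delay"].to_numpy())
    p_ll = choice_prob(sv, params.beta_temp, SS_AMOUNT)
    chose_ll = rng.random(len(design)) < p_ll
    out = design.copy()
    out.insert(0, "participant_id", participant_id)
    out.insert(1, "group", group)
    out.insert(2, "session", session)
    out["choice"] = np.where(chose_ll, "LL", "SS")
    return out[CHOICE_TABLE_COLUMNS]


def simulate_timetravel_rts(config: CohortConfig,
                            params: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate the cohort's time-travel RT table under the log-RT model.

    See :class:`RtEffects` for the generative equation.  RTs are truncated to
    the 3-second response window; omissions are not generated.
    """
    eff = config.rt_effects
    if params is not None:
        u_by_pid = params.drop_duplicates("participant_id").set_index("participant_id")["u"]
    else:
        u_by_pid = None
    frames = []
    for _, row in _participant_ids(config).iterrows():
        pid, group = row["participant_id"], row["group"]
        r = substream(config.seed, "rt", pid)
        p_int = eff.participant_sd * r.standard_normal()
        if u_by_pid is not None and pid in u_by_pid.index:
            u = float(u_by_pid[pid])
        else:
            u = float(r.standard_normal())
        three_way = eff.group_x_session_x_event_time * (1.0 + config.susceptibility_sd * u)
        for session in ("pre", "post"):
            design = make_timetravel_design(config.events_per_cell,
                                            rng=substream(config.seed, "ttdesign", pid, session))
            is_post = float(session == "post")
            et = (design["event_time"] == "future").to_numpy(dtype=float)
            log_rt = (
                eff.intercept
                + p_int
                + eff.perspective_future * (design["perspective"] == "future").to_numpy(dtype=float)
                + eff.event_type_nonpersonal * (design["event_type"] == "nonpersonal").to_numpy(dtype=float)
                + eff.event_time_future * et
                + eff.session_x_event_time * is_post * et
                + (three_way if group == "rTPJ" else 0.0) * is_post * et
                + eff.noise_sd * r.standard_normal(len(design))
            )
            rt = np.minimum(np.exp(log_rt), RESPONSE_WINDOW)
            out = design.copy()
            out.insert(0, "participant_id", pid)
            out.insert(1, "group", group)
            out.insert(2, "session", session)
            out["rt"] = rt
            out["log_rt"] = np.log(rt)
            frames.append(out[RT_TABLE_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: CohortConfig) -> dict:
    """Generate the complete synthetic study.

    Returns a dict with ``choices`` (trial-level choice table), ``rts``
    (time-travel RT table), ``params`` (true per-participant parameters) and
    ``manifest`` (config echo).
    """
    params = sample_participant_params(config)
    frames = []
    for _, row in params.iterrows():
        pid, group, session = row["participant_id"], row["group"], row["session"]
        true = DiscountParams(model="generalized_hyperbolic", k=row["k"], s=row["s"],
                              beta_temp=row["beta_temp"])
        design = make_choice_design(
            config.reward_grid, config.delay_grid, config.repeats_per_session,
            rng=substream(config.seed, "design", pid, session),
        )
        frames.append(simulate_choices(
            true, design, substream(config.seed, "choices", pid, session),
            participant_id=pid, group=group, session=session,
        ))
    choices = pd.concat(frames, ignore_index=True)
    rts = simulate_timetravel_rts(config, params)
    manifest = {"config": config.to_dict(), "n_participants": 2 * config.n_per_group}
    return {"choices": choices, "rts": rts, "params": params, "manifest": manifest}


def write_cohort(cohort: dict, out_dir) -> dict:
    """Write cohort tables as CSV plus a manifest JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "choices": out / "choices.csv",
        "rts": out / "rts.csv",
        "params": out / "true_params.csv",
        "manifest": out / "manifest.json",
    }
    cohort["choices"].to_csv(paths["choices"], index=False)
    cohort["rts"].to_csv(paths["rts"], index=False)
    cohort["params"].to_csv(paths["params"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(cohort["manifest"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
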