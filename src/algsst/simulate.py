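"""Synthetic standard stop-signal-task sessions under the independent race model.

A session is a fixed design of blocks x trials with a fixed fraction of
stop trials.  On every trial a go latency ``Tgo`` is drawn from the
Ex-Gaussian of the trial's type: type A (previous within-block trial was a
go, or the trial opens a block) uses ``theta_A``; type B (previous trial
was a stop) uses ``theta_B``.  Proactive slowing is therefore injected
mechanically as a trial-type-dependent go distribution.  On stop trials a
stop latency ``Tstop`` is drawn and the race decides the outcome:
inhibition succeeds iff ``Tgo > Tstop + SSD``.  The stop-signal delay
follows the usual one-up/one-down staircase (+step after a success, -step
after a failure, floored at zero), which drives the long-run success rate
to 50%.  Contextual independence holds by construction: the go draw never
depends on the SSD.

Defaults reproduce a 4-block x 24-trial design with 25% stop trials and
type-A/type-B go components at the group-mean Ex-Gaussian values of the
motivating stop-signal dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import ExGParams

__all__ = [
    "ConfigurationError",
    "SSTConfig",
    "TrialRecord",
    "SSTSession",
    "place_stop_trials",
    "simulate_session",
    "simulate_cohort",
    "sessions_to_frame",
    "write_trials_csv",
    "read_trials_csv",
]

CSV_COLUMNS = ["participant", "block", "position", "trial_type",
               "ssd", "go_rt", "inhibited", "cluster"]


class ConfigurationError(ValueError):
    """Raised for infeasible or invalid session configurations."""


def _default_theta_a() -> ExGParams:
    return ExGParams(478.8, 109.9, 104.2)


def _default_theta_b() -> ExGParams:
    return ExGParams(532.8, 133.1, 142.4)


def _default_theta_stop() -> ExGParams:
    return ExGParams(200.0, 30.0, 40.0)


@dataclass
class SSTConfig:
    """Design constants and generating parameters of one simulated session.

    ``ssd_step`` is a conventional staircase step (ms).  ``ssd_initial``
    defaults to ``None``, meaning the staircase starts at the generating
    model's own 50% tracking point (see :meth:`tracking_ssd`): the delay
    at which the race ``Tgo > Tstop + SSD`` succeeds with probability one
    half under the session's stop-trial context mixture.  Starting at that
    equilibrium is what makes the session-long success proportion track
    the designed 50%; an explicit numeric start is honoured as given.  ``adjacency_target`` optionally fixes the number of stop
    trials that immediately follow another stop trial, to emulate cohorts
    selected for an almost balanced type-B trial count.
    ``p_go_omission`` is the probability that a go trial goes unanswered
    (off by default; omitted responses carry no RT).
    """

    n_blocks: int = 4
    trials_per_block: int = 24
    p_stop: float = 0.25
    ssd_initial: Optional[float] = None
    ssd_step: float = 50.0
    theta_A: ExGParams = field(default_factory=_default_theta_a)
    theta_B: ExGParams = field(default_factory=_default_theta_b)
    theta_stop: ExGParams = field(default_factory=_default_theta_stop)
    no_block_final_stop: bool = True
    adjacency_target: Optional[int] = None
    p_go_omission: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.trials_per_block < 2:
            raise ConfigurationError("trials_per_block must be >= 2")
        if not 0.0 < self.p_stop < 1.0:
            raise ConfigurationError("p_stop must be in (0, 1)")
        if self.ssd_step <= 0:
            raise ConfigurationError("ssd_step must be > 0")
        if self.ssd_initial is not None and self.ssd_initial < 0:
            raise ConfigurationError("ssd_initial must be >= 0")
        if not 0.0 <= self.p_go_omission < 1.0:
            raise ConfigurationError("p_go_omission must be in [0, 1)")
        for name in ("theta_A", "theta_B", "theta_stop"):
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, ExGParams.from_dict(val))

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def tracking_ssd(self) -> float:
        """Delay at which the race succeeds with probability 1/2.

        ``Tgo - Tstop`` for independent Ex-Gaussian processes is an
        Asymmetric Laplace Gaussian, so the 50% point solves
        ``P(Tgo - Tstop > s) = 1/2`` under the stop-trial context mixture
        (a fraction ``p_stop`` of stop trials follow a stop trial and draw
        the type-B go distribution).  Floored at zero.
        """
        from scipy.optimize import brentq

        from .distributions import alg_from_components, alg_sf, alg_stats

        diff_a = alg_from_components(self.theta_stop, self.theta_A)
        diff_b = alg_from_components(self.theta_stop, self.theta_B)
        w_b = self.p_stop
        sd = max(alg_stats(diff_a).sd, alg_stats(diff_b).sd)
        centre = (1 - w_b) * alg_stats(diff_a).mean + w_b * alg_stats(diff_b).mean

        def excess(s: float) -> float:
            return ((1 - w_b) * alg_sf(s, diff_a)
                    + w_b * alg_sf(s, diff_b) - 0.5)

        root = brentq(excess, centre - 15 * sd, centre + 15 * sd)
        return max(0.0, float(root))

    def initial_ssd(self) -> float:
        return (self.tracking_ssd() if self.ssd_initial is None
                else float(self.ssd_initial))

    @property
    def n_stop(self) -> int:
        return round(self.p_stop * self.n_trials)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SSTConfig":
        return cls(**json.loads(text))


@dataclass
class TrialRecord:
    """One trial of a session.

    ``go_rt`` is the observed response latency: present on every answered
    go trial and on failed stop trials, absent after successful inhibition
    (the response was withheld) or an omission.  ``tgo``/``tstop`` log the
    underlying race draws for auditing; they are not written to CSV.
    """

    block: int
    position: int
    trial_type: str               # "go" | "stop"
    ssd: Optional[float] = None   # stop trials only
    go_rt: Optional[float] = None
    inhibited: Optional[bool] = None
    cluster: Optional[str] = None  # "A" | "B", filled by partitioning
    tgo: Optional[float] = None
    tstop: Optional[float] = None


@dataclass
class SSTSession:
    """Ordered trials of one participant plus the generating configuration."""

    participant: int
    trials: list[TrialRecord]
    config: SSTConfig

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_stop_trials(self) -> int:
        return sum(1 for t in self.trials if t.trial_type == "stop")

    @property
    def inhibition_rate(self) -> float:
        stops = [t for t in self.trials if t.trial_type == "stop"]
        return float(np.mean([t.inhibited for t in stops])) if stops else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "participant": self.participant,
                "block": t.block,
                "position": t.position,
                "trial_type": t.trial_type,
                "ssd": t.ssd,
                "go_rt": t.go_rt,
                "inhibited": t.inhibited,
                "cluster": t.cluster,
            })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def place_stop_trials(config: SSTConfig, rng=None) -> list[int]:
    """Choose the global (0-based) positions of the stop trials.

    Exactly ``round(p_stop * n_trials)`` positions are returned, never in
    block-final position when ``no_block_final_stop`` is set.  With
    ``adjacency_target = k`` the stops form exactly ``n_stop - k`` maximal
    within-block runs, so exactly ``k`` stops immediately follow a stop;
    runs are placed by a randomised stars-and-bars construction with
    bounded retries.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n, tpb, m = config.n_trials, config.trials_per_block, config.n_stop
    if m < 1:
        raise ConfigurationError("configuration yields zero stop trials")
    finals = {b * tpb + (tpb - 1) for b in range(config.n_blocks)}

    if config.adjacency_target is None:
        allowed = [i for i in range(n) if not (config.no_block_final_stop and i in finals)]
        if m > len(allowed):
            raise ConfigurationError("more stop trials than allowed positions")
        return sorted(int(i) for i in rng.choice(allowed, size=m, replace=False))

    k = int(config.adjacency_target)
    if not 0 <= k <= m - 1:
        raise ConfigurationError(f"adjacency_target must be in [0, {m - 1}], got {k}")
    n_runs = m - k
    for _ in range(500):
        # random composition of m stops into n_runs positive run lengths
        if n_runs > 1:
            cuts = rng.choice(np.arange(1, m), size=n_runs - 1, replace=False)
            bounds = np.concatenate(([0], np.sort(cuts), [m]))
            lengths = np.diff(bounds)
        else:
            lengths = np.array([m])
        blocks = rng.integers(0, config.n_blocks, size=n_runs)
        positions: list[int] = []
        ok = True
        for b in range(config.n_blocks):
            runs_here = lengths[blocks == b]
            q = len(runs_here)
            if q == 0:
                continue
            g = tpb - int(runs_here.sum())  # go trials left in the block
            n_slots = g if config.no_block_final_stop else g + 1
            if g < 0 or q > n_slots:
                ok = False
                break
            # slot i = "run emitted after i gos"; distinct slots guarantee a
            # go between runs, so runs stay maximal and adjacency is exact
            slots = np.sort(rng.choice(n_slots, size=q, replace=False))
            lengths_at_slot = dict(zip(slots.tolist(),
                                       runs_here[rng.permutation(q)].tolist()))
            pos_in_block = 0
            for gos_emitted in range(g + 1):
                run_len = lengths_at_slot.get(gos_emitted)
                if run_len is not None:
                    start = b * tpb + pos_in_block
                    positions.extend(range(start, start + int(run_len)))
                    pos_in_block += int(run_len)
                if gos_emitted < g:
                    pos_in_block += 1  # emit one go
        if ok and len(positions) == m:
            return sorted(positions)
    raise ConfigurationError(
        "could not place stop trials under the adjacency/feasibility constraints")


def count_stop_adjacencies(stop_positions: Sequence[int], config: SSTConfig) -> int:
    """Number of stops whose within-block predecessor is also a stop."""
    stops = set(stop_positions)
    tpb = config.trials_per_block
    return sum(1 for i in stops if i % tpb != 0 and (i - 1) in stops)


def simulate_session(config: SSTConfig, participant: int = 0,
                     rng=None) -> SSTSession:
    """Simulate one session under the independent race model.

    The staircase SSD carries over across blocks; the go draw distribution
    is decided by the previous within-block trial's type (block-initial
    trials count as type A context).
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    stop_positions = set(place_stop_trials(config, rng))
    ssd = config.initial_ssd()
    trials: list[TrialRecord] = []
    for i in range(config.n_trials):
        block = i // config.trials_per_block
        pos = i % config.trials_per_block
        after_stop = pos > 0 and (i - 1) in stop_positions
        theta = config.theta_B if after_stop else config.theta_A
        tgo = rng.normal(theta.mu, theta.sigma) + rng.exponential(theta.tau)
        if i in stop_positions:
            ts = config.theta_stop
            tstop = rng.normal(ts.mu, ts.sigma) + rng.exponential(ts.tau)
            inhibited = bool(tgo > tstop + ssd)
            rec = TrialRecord(block=block, position=pos, trial_type="stop",
                              ssd=ssd, go_rt=None if inhibited else tgo,
                              inhibited=inhibited, tgo=tgo, tstop=tstop)
            ssd = ssd + config.ssd_step if inhibited else max(0.0, ssd - config.ssd_step)
        else:
            omitted = config.p_go_omission > 0 and rng.random() < config.p_go_omission
            rec = TrialRecord(block=block, position=pos, trial_type="go",
                              go_rt=None if omitted else tgo, tgo=tgo)
        trials.append(rec)
    return SSTSession(participant=participant, trials=trials, config=config)


ThetaSampler = Callable[[np.random.Generator], tuple[ExGParams, ExGParams]]


def simulate_cohort(config: SSTConfig, n_participants: int,
                    seed: Optional[int] = None,
                    theta_sampler: Optional[ThetaSampler] = None) -> list[SSTSession]:
    """Simulate independent sessions with per-participant child seeds.

    ``theta_sampler``, if given, draws ``(theta_A, theta_B)`` per
    participant (between-participant heterogeneity); otherwise every
    session shares the configuration's parameters.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    master = seed if seed is not None else config.seed
    children = np.random.SeedSequence(master).spawn(n_participants)
    sessions = []
    for pid, child in enumerate(children):
        rng = np.random.default_rng(child)
        cfg = config
        if theta_sampler is not None:
            theta_a, theta_b = theta_sampler(rng)
            cfg = dataclasses.replace(config, theta_A=theta_a, theta_B=theta_b)
        sessions.append(simulate_session(cfg, participant=pid, rng=rng))
    return sessions


def sessions_to_frame(sessions: Sequence[SSTSession]) -> pd.DataFrame:
    """Stack sessions into one tidy trial table."""
    rows = [row for s in sessions
            for row in s.to_frame().to_dict(orient="records")]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_trials_csv(sessions: Sequence[SSTSession], path) -> None:
    """Write the trial table (missing values empty, times in ms)."""
    sessions_to_frame(sessions).to_csv(Path(path), index=False)


def read_trials_csv(path) -> pd.DataFrame:
    """Read a trial table in the dialect written by :func:`write_trials_csv`."""
    df = pd.read_csv(Path(path))
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing - {"cluster"}:
        raise ConfigurationError(f"trial table missing columns: {sorted(missing)}")
    if "cluster" not in df.columns:
        df["cluster"] = pd.NA
    return df[CSV_COLUMNS]
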