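"""Trial-type partitioning and go-RT (GORT) extraction.

A trial is **type B** iff the immediately preceding trial *in the same
block* is a stop trial; block-initial trials and trials preceded by a go
trial are **type A**.  The labels cover every trial, go and stop alike.
The cluster go-RT vectors ``GORT_A`` / ``GORT_B`` collect the latencies of
*go* trials only — responses on stop trials (failed inhibitions) are not
go-trial RTs and are excluded by default.  The constant proactive-
inhibition index is ``mean(GORT_B) - mean(GORT_A)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SSTSession

__all__ = [
    "ClusteringError",
    "ClusteredGORT",
    "partition",
    "partition_frame",
    "extract_gort",
    "extract_gort_frame",
    "tt_proactive_index",
]


class ClusteringError(ValueError):
    """Raised on malformed sessions or undefined cluster quantities."""


@dataclass
class ClusteredGORT:
    """Cluster go-RT vectors and bookkeeping counts for one participant.

    ``n_a_trials``/``n_b_trials`` count *all* trials per label;
    ``n_a_stop``/``n_b_stop`` count the stop trials among them;
    ``n_dropped`` counts responded RTs discarded as missing/non-positive.
    """

    gort_a: np.ndarray
    gort_b: np.ndarray
    n_a_trials: int
    n_b_trials: int
    n_a_stop: int
    n_b_stop: int
    n_dropped: int = 0

    @property
    def has_empty_cluster(self) -> bool:
        return len(self.gort_a) == 0 or len(self.gort_b) == 0

    def summary(self) -> dict:
        return {
            "n_gort_a": int(len(self.gort_a)),
            "n_gort_b": int(len(self.gort_b)),
            "n_a_trials": self.n_a_trials,
            "n_b_trials": self.n_b_trials,
            "n_a_stop": self.n_a_stop,
            "n_b_stop": self.n_b_stop,
            "n_dropped": self.n_dropped,
        }


def _check_ordered(blocks, positions) -> None:
    seen = set()
    prev = None
    for b, p in zip(blocks, positions):
        key = (b, p)
        if key in seen:
            raise ClusteringError(f"duplicate trial at block {b}, position {p}")
        seen.add(key)
        if prev is not None and key < prev:
            raise ClusteringError("trials are not ordered by block and position")
        prev = key


def partition(session: SSTSession) -> SSTSession:
    """Label every trial of a session as cluster A or B, in place.

    Deterministic and idempotent: relabelling a labelled session changes
    nothing.  Blocks are independent sequences — the first trial of each
    block is type A even if the previous block ended in a stop trial.
    """
    _check_ordered([t.block for t in session.trials],
                   [t.position for t in session.trials])
    prev_key = None
    prev_type = None
    for t in session.trials:
        first_of_block = prev_key is None or prev_key[0] != t.block
        t.cluster = "B" if (not first_of_block and prev_type == "stop") else "A"
        prev_key = (t.block, t.position)
        prev_type = t.trial_type
    return session


def partition_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`partition` for a tidy trial table.

    Requires columns ``participant, block, position, trial_type``; returns
    a copy with the ``cluster`` column filled.
    """
    out = df.copy()
    out = out.sort_values(["participant", "block", "position"], kind="stable")
    dup = out.duplicated(subset=["participant", "block", "position"])
    if dup.any():
        raise ClusteringError("duplicate (participant, block, position) rows")
    grp = out.groupby(["participant", "block"], sort=False)
    prev_is_stop = grp["trial_type"].shift(1).eq("stop")
    out["cluster"] = np.where(prev_is_stop, "B", "A")
    return out


def extract_gort(session: SSTSession,
                 include_failed_stop_rts: bool = False) -> ClusteredGORT:
    """Extract cluster go-RT vectors from a labelled session.

    Only responded go trials contribute RTs; failed-stop responses can be
    added back with ``include_failed_stop_rts`` for sensitivity analysis.
    Missing or non-positive RTs are dropped and counted.
    """
    if any(t.cluster not in ("A", "B") for t in session.trials):
        partition(session)
    vecs = {"A": [], "B": []}
    counts = {"A": 0, "B": 0}
    stops = {"A": 0, "B": 0}
    dropped = 0
    for t in session.trials:
        counts[t.cluster] += 1
        if t.trial_type == "stop":
            stops[t.cluster] += 1
            if not include_failed_stop_rts:
                continue
            if t.inhibited or t.go_rt is None:
                continue
        rt = t.go_rt
        if t.trial_type == "go" or include_failed_stop_rts:
            if rt is None or not np.isfinite(rt) or rt <= 0:
                if rt is not None or t.trial_type == "go":
                    dropped += 1
                continue
            vecs[t.cluster].append(float(rt))
    return ClusteredGORT(
        gort_a=np.asarray(vecs["A"], dtype=float),
        gort_b=np.asarray(vecs["B"], dtype=float),
        n_a_trials=counts["A"],
        n_b_trials=counts["B"],
        n_a_stop=stops["A"],
        n_b_stop=stops["B"],
        n_dropped=dropped,
    )


def extract_gort_frame(df: pd.DataFrame, participant,
                       include_failed_stop_rts: bool = False) -> ClusteredGORT:
    """:func:`extract_gort` for one participant of a labelled trial table."""
    sub = df[df["participant"] == participant]
    if sub.empty:
        raise ClusteringError(f"no trials for participant {participant!r}")
    if sub["cluster"].isna().any():
        sub = partition_frame(sub)
    is_go = sub["trial_type"].eq("go")
    rows = sub[is_go | include_failed_stop_rts & sub["trial_type"].eq("stop")
               & ~sub["inhibited"].astype("boolean").fillna(True).astype(bool)]
    rt = pd.to_numeric(rows["go_rt"], errors="coerce")
    valid = rt.notna() & (rt > 0)
    dropped = int(((~valid) & rows["trial_type"].eq("go")).sum())
    rows = rows[valid]
    rt = rt[valid]
    return ClusteredGORT(
        gort_a=rt[rows["cluster"] == "A"].to_numpy(dtype=float),
        gort_b=rt[rows["cluster"] == "B"].to_numpy(dtype=float),
        n_a_trials=int((sub["cluster"] == "A").sum()),
        n_b_trials=int((sub["cluster"] == "B").sum()),
        n_a_stop=int(((sub["cluster"] == "A") & sub["trial_type"].eq("stop")).sum()),
        n_b_stop=int(((sub["cluster"] == "B") & sub["trial_type"].eq("stop")).sum()),
        n_dropped=dropped,
    )


def tt_proactive_index(c: ClusteredGORT) -> float:
    """Constant (trial-type) proactive-inhibition index, ms.

    ``mean(GORT_B) - mean(GORT_A)`` — the expectation of the
    distributional index ``GORT_B - GORT_A``.
    """
    if c.has_empty_cluster:
        raise ClusteringError("proactive index undefined: empty GORT cluster")
    return float(np.mean(c.gort_b) - np.mean(c.gort_a))
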