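"""The adaptation + approximate-scale-invariance computational screen.

Protocol per circuit: pre-adapt to a background input u0, apply a 20% step to
1.2*u0, and require precision error E <= 0.1 together with sensitivity
S >= 1 for the circuit to count as adapting.  Adapting circuits are then
re-tested from a scaled background p*u0 (20% step to 1.2*p*u0); the circuit
is approximately scale invariant (ASI) when the two output transients differ
by at most 10% of the reference transient amplitude.

Parameters are Latin-hypercube sampled in log space, one (k, K) pair per
regulatory interaction; the whole screen is deterministic in its master seed
and order-independent across topologies (per-topology RNG substreams).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .enzyme_model import (
    Circuit,
    CircuitParams,
    IntegrationError,
    build_system,
    implied_interactions,
    steady_state,
    _odeint_segment,
    DEFAULT_RTOL,
    DEFAULT_ATOL,
)
from .metrics import (
    ASI_THRESHOLD,
    OUTPUT_FLOOR,
    PRECISION_THRESHOLD,
    SENSITIVITY_THRESHOLD,
    StepResponseSummary,
    UndefinedMetric,
    asi_error,
    precision_error,
    sensitivity,
)
from .topology import (
    Topology,
    classify_motifs,
    from_index,
    retained_topology_indices,
    topology_index,
)


@dataclass
class ScreenConfig:
    k_range: tuple = (0.1, 10.0)
    K_range: tuple = (1e-3, 100.0)
    n_params: int = 10000
    u0: float = 0.5
    p_scale: float = 2.0
    step_fraction: float = 0.2
    precision_threshold: float = PRECISION_THRESHOLD
    sensitivity_threshold: float = SENSITIVITY_THRESHOLD
    asi_threshold: float = ASI_THRESHOLD
    seed: int = 0
    t_max: float = 1e4
    ss_tol: float = 1e-9
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    points_per_chunk: int = 120

    def __post_init__(self):
        if self.k_range[0] <= 0 or self.K_range[0] <= 0:
            raise ValueError("sampling ranges must be positive")


def planned_circuit_count(cfg: ScreenConfig, n_topologies: int = None) -> int:
    """Total number of circuits a configured screen will visit."""
    if n_topologies is None:
        n_topologies = len(retained_topology_indices())
    return n_topologies * cfg.n_params


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def sample_params(t: Topology, n: int, seed: int,
                  k_range=(0.1, 10.0), K_range=(1e-3, 100.0)) -> list:
    """Latin hypercube sample of n parameter sets for a topology.

    One dimension per rate constant of every implied interaction (catalytic k
    and Michaelis K, including constitutive enzymes and the input term),
    stratified uniformly in log10 space; fully determined by
    (seed, topology index, n).
    """
    inter = implied_interactions(t)
    d = 2 * len(inter)
    rng = np.random.default_rng(np.random.SeedSequence([seed, topology_index(t), n]))
    unit = qmc.LatinHypercube(d=d, seed=rng).random(n)
    lo = np.empty(d)
    hi = np.empty(d)
    lo[0::2], hi[0::2] = np.log10(k_range[0]), np.log10(k_range[1])
    lo[1::2], hi[1::2] = np.log10(K_range[0]), np.log10(K_range[1])
    vals = 10.0 ** (lo + unit * (hi - lo))
    out = []
    for row in vals:
        out.append(CircuitParams(
            {it.name: (row[2 * i], row[2 * i + 1]) for i, it in enumerate(inter)}))
    return out


# ---------------------------------------------------------------------------
# Step experiments
# ---------------------------------------------------------------------------

#: Post-step integration horizons, probed in sequence until the circuit
#: re-settles (residual below the steady-state tolerance).
_RESPONSE_CHUNKS = (20.0, 80.0, 400.0, 1500.0, 8000.0)


@dataclass
class StepExperiment:
    """Raw material of one step experiment: settle state + response series."""

    summary: StepResponseSummary
    t: np.ndarray          # post-step times
    y: np.ndarray          # output series
    x_pre: np.ndarray      # pre-adapted state
    reason: str = "ok"


def _chunk_grid(dt: float, n: int, first: bool) -> np.ndarray:
    """Reporting grid for one chunk.  The first chunk is log-dense near the
    step so that fast transient peaks (relaxation rates up to k/K ~ 1e4)
    are resolved; later chunks are linear."""
    if not first:
        return np.linspace(0.0, dt, n)
    n_log = n // 2
    log_part = np.geomspace(dt * 1e-5, dt * 0.1, n_log)
    lin_part = np.linspace(dt * 0.1, dt, n - n_log)[1:]
    return np.concatenate([[0.0], log_part, lin_part])


def _step_response(system, x_pre, u1, cfg: ScreenConfig):
    """Integrate the post-step response in growing chunks until re-settled."""
    ts, ys = [], []
    x = np.asarray(x_pre, dtype=float)
    t0 = 0.0
    settled = False
    for dt in _RESPONSE_CHUNKS:
        if t0 >= cfg.t_max:
            break
        dt = min(dt, cfg.t_max - t0)
        grid = _chunk_grid(dt, cfg.points_per_chunk, first=not ts)
        seg = _odeint_segment(system, x, u1, grid, cfg.rtol, cfg.atol)
        start = 1 if ts else 0
        ts.append(t0 + grid[start:])
        ys.append(seg[start:, system.output])
        x = seg[-1]
        t0 += dt
        if np.max(np.abs(system.rhs(x, u1))) < cfg.ss_tol:
            settled = True
            break
    return np.concatenate(ts), np.concatenate(ys), x, settled


def run_step_experiment(system, u_base: float, cfg: ScreenConfig):
    """Pre-adapt at ``u_base`` and apply the configured relative step."""
    ss = steady_state(system, u_base, tol=cfg.ss_tol, t_max=cfg.t_max,
                      rtol=cfg.rtol, atol=cfg.atol)
    if not ss.converged:
        return None, "no_preadapt_steady_state"
    u1 = u_base * (1.0 + cfg.step_fraction)
    O1 = float(ss.x[system.output])
    try:
        t, y, x_end, settled = _step_response(system, ss.x, u1, cfg)
    except IntegrationError:
        return None, "integration_failure"
    ipeak = int(np.argmax(np.abs(y - O1)))
    summary = StepResponseSummary(O1=O1, Opeak=float(y[ipeak]), O2=float(y[-1]),
                                  u1=u_base, u2=u1, settled=settled)
    return StepExperiment(summary=summary, t=t, y=y, x_pre=ss.x), "ok"


@dataclass
class AdaptationResult:
    adapts: bool
    E: float = np.nan
    S: float = np.nan
    reason: str = "ok"
    experiment: StepExperiment = None

    @property
    def summary(self):
        return self.experiment.summary if self.experiment else None


def run_adaptation_test(c, cfg: ScreenConfig = None) -> AdaptationResult:
    """The 20% step adaptation test: E <= 0.1, S >= 1, re-settled."""
    cfg = cfg or ScreenConfig()
    system = build_system(c) if isinstance(c, Circuit) else c
    exp, reason = run_step_experiment(system, cfg.u0, cfg)
    if exp is None:
        return AdaptationResult(False, reason=reason)
    s = exp.summary
    if abs(s.O1) < OUTPUT_FLOOR:
        return AdaptationResult(False, reason="zero_baseline", experiment=exp)
    try:
        E = precision_error(s)
        S = sensitivity(s)
    except UndefinedMetric:
        return AdaptationResult(False, reason="undefined_metric", experiment=exp)
    if not s.settled:
        return AdaptationResult(False, E=E, S=S, reason="no_resettle",
                                experiment=exp)
    adapts = (E <= cfg.precision_threshold and S >= cfg.sensitivity_threshold)
    return AdaptationResult(adapts, E=E, S=S, experiment=exp)


@dataclass
class AsiResult:
    asi: bool
    rho: float = np.nan
    reason: str = "ok"


def run_asi_test(c, cfg: ScreenConfig = None,
                 base: AdaptationResult = None) -> AsiResult:
    """Repeat the step protocol from a scaled background and compare outputs.

    The scaled experiment (p*u0 -> 1.2*p*u0) is evaluated on the baseline's
    post-step time grid, so the two output series align at the step time.
    """
    cfg = cfg or ScreenConfig()
    system = build_system(c) if isinstance(c, Circuit) else c
    if base is None or base.experiment is None:
        base = run_adaptation_test(system, cfg)
        if base.experiment is None:
            return AsiResult(False, reason=base.reason)
    exp = base.experiment
    u_base = cfg.p_scale * cfg.u0
    ss2 = steady_state(system, u_base, tol=cfg.ss_tol, t_max=cfg.t_max,
                       rtol=cfg.rtol, atol=cfg.atol)
    if not ss2.converged:
        return AsiResult(False, reason="no_scaled_steady_state")
    u1 = u_base * (1.0 + cfg.step_fraction)
    grid = np.concatenate([[0.0], exp.t]) if exp.t[0] > 0 else exp.t
    try:
        seg = _odeint_segment(system, ss2.x, u1, grid, cfg.rtol, cfg.atol)
    except IntegrationError:
        return AsiResult(False, reason="integration_failure")
    y_scaled = seg[(1 if exp.t[0] > 0 else 0):, system.output]
    try:
        rho = asi_error(exp.y, y_scaled, y_ref_baseline=exp.summary.O1)
    except UndefinedMetric:
        return AsiResult(False, reason="zero_reference_amplitude")
    return AsiResult(rho <= cfg.asi_threshold, rho=rho)


# ---------------------------------------------------------------------------
# Full screen
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "topology_index", "param_id", "seed", "u0",
    "O1", "Opeak", "O2", "E", "S", "rho",
    "adapts", "asi", "reason",
]


def screen_circuit(c, cfg: ScreenConfig) -> dict:
    """Classify one circuit; always returns a complete record."""
    system = build_system(c) if isinstance(c, Circuit) else c
    ad = run_adaptation_test(system, cfg)
    rec = {
        "topology_index": c.meta.get("topology_index",
                                     topology_index(c.topology))
        if isinstance(c, Circuit) else -1,
        "param_id": c.meta.get("param_id", -1) if isinstance(c, Circuit) else -1,
        "seed": cfg.seed,
        "u0": cfg.u0,
        "O1": np.nan, "Opeak": np.nan, "O2": np.nan,
        "E": ad.E, "S": ad.S, "rho": np.nan,
        "adapts": ad.adapts, "asi": False, "reason": ad.reason,
    }
    if ad.summary is not None:
        rec["O1"] = ad.summary.O1
        rec["Opeak"] = ad.summary.Opeak
        rec["O2"] = ad.summary.O2
    if ad.adapts:
        asi = run_asi_test(system, cfg, base=ad)
        rec["rho"] = asi.rho
        rec["asi"] = asi.asi
        if asi.reason != "ok":
            rec["reason"] = asi.reason
    return rec


def full_screen(cfg: ScreenConfig, topologies=None, out_csv=None,
                log=None, log_every: int = 1000) -> tuple:
    """Run the screen over topologies x Latin-hypercube parameter draws.

    ``topologies`` defaults to every topology with an input-to-output path.
    Writes a streaming CSV when ``out_csv`` is given (floats at 17 significant
    digits).  Returns (records DataFrame, summary dict).  Deterministic in
    (cfg.seed, topology set, cfg.n_params); topology order is irrelevant to
    the draws because each topology owns an RNG substream.
    """
    if topologies is None:
        topologies = retained_topology_indices()
    t_start = time.time()
    rows = []
    handle = open(out_csv, "w") if out_csv else None
    if handle:
        handle.write(",".join(RECORD_COLUMNS) + "\n")
    count = 0
    try:
        for t_idx in topologies:
            topo = from_index(int(t_idx))
            if cfg.n_params <= 0:
                continue
            draws = sample_params(topo, cfg.n_params, cfg.seed,
                                  cfg.k_range, cfg.K_range)
            for pid, params in enumerate(draws):
                c = Circuit(topo, params,
                            meta={"topology_index": int(t_idx), "param_id": pid})
                rec = screen_circuit(c, cfg)
                rows.append(rec)
                if handle:
                    handle.write(_format_row(rec) + "\n")
                count += 1
                if log and count % log_every == 0:
                    log(f"screened {count} circuits "
                        f"({time.time() - t_start:.0f}s elapsed)")
    finally:
        if handle:
            handle.close()
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df, summarize_screen(df)


def _format_row(rec: dict) -> str:
    out = []
    for col in RECORD_COLUMNS:
        v = rec[col]
        if isinstance(v, (bool, np.bool_)):
            out.append(str(bool(v)))
        elif isinstance(v, (float, np.floating)):
            out.append(f"{v:.17g}")
        else:
            out.append(str(v))
    return ",".join(out)


def summarize_screen(df: pd.DataFrame) -> dict:
    """Counts and fractions of the screen outcome."""
    n = len(df)
    n_adapt = int(df["adapts"].sum()) if n else 0
    n_asi = int(df["asi"].sum()) if n else 0
    asi_topos = sorted(df.loc[df["asi"], "topology_index"].unique().tolist()) \
        if n else []
    return {
        "n_circuits": n,
        "n_adapting": n_adapt,
        "n_asi": n_asi,
        "adapting_fraction": n_adapt / n if n else 0.0,
        "asi_fraction_of_adapting": (n_asi / n_adapt) if n_adapt else 0.0,
        "n_asi_topologies": len(asi_topos),
        "asi_topology_indices": asi_topos,
    }


def check_asi_structure(df: pd.DataFrame) -> pd.DataFrame:
    """Structural audit of every asi=True record.

    Scale-invariant circuits are expected to carry an incoherent feedforward
    motif with a nested negative feedback loop between B and C; violations
    are returned (not dropped) for inspection.
    """
    checks = []
    for _, row in df.loc[df["asi"]].iterrows():
        flags = classify_motifs(from_index(int(row["topology_index"])))
        checks.append({
            "topology_index": int(row["topology_index"]),
            "param_id": int(row["param_id"]),
            "is_feedforward": flags.is_feedforward,
            "is_incoherent": flags.is_incoherent,
            "has_nested_feedback": flags.has_nested_negative_BC_loop,
        })
    return pd.DataFrame(checks,
                        columns=["topology_index", "param_id", "is_feedforward",
                                 "is_incoherent", "has_nested_feedback"])
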