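"""Simulation campaigns: single points, parameter-plane sweeps, showcases.

``run_point`` composes the pipeline for one parameter set: integrate the
coupled system from (seeded) random initial conditions, discard a
transient, count firings, compute the omega-sorted mean-phase-velocity
profile, and evaluate the spatial coherence g0(t), its average g1 and the
per-layer classification.

``run_sweep`` maps ``run_point`` over a 1- or 2-axis grid (axes among
lambda_in, lambda_out, alpha, l_out), optionally averaging replicates with
distinct seeds, writing a resumable long-format CSV as it goes.  When the
axis is the inter-link count, the inter-layer link sets are nested by
default (a larger count contains the smaller count's links) so that the
axis is not confounded by independent link realizations.

``regime_showcase`` runs the four canonical coupling-strength scenarios
(disorder, chimera, unihemispheric-sleep-like, synchronized) at
alpha = pi/2 - 0.1.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    FHNParameters,
    SystemState,
    integrate,
    random_initial_conditions,
)
from .network_model import (
    LayeredNetwork,
    add_interlayer_links,
    interlayer_pair_permutation,
)
from .observables import (
    CoherenceResult,
    coherence_from_samples,
    velocity_profile,
)

#: canonical coupling-strength scenarios (lambda_in, lambda_out) at
#: alpha = pi/2 - 0.1
SCENARIOS = {
    "disorder": (0.1, 0.3),
    "chimera": (0.1, 1.8),
    "unihemispheric": (0.4, 3.5),
    "sync": (4.0, 3.5),
}

SWEEPABLE = ("lambda_in", "lambda_out", "alpha", "l_out")


@dataclass(frozen=True)
class RunConfig:
    """Integration and measurement settings for one simulation point.

    Times are in dimensionless model time.  The first ``t_trans`` units are
    discarded; diagnostics use the following ``t_measure`` units sampled
    every ``sample_every`` units.
    """

    dt: float = 0.01
    t_trans: float = 1000.0
    t_measure: float = 2000.0
    sample_every: float = 0.5
    firing_threshold: float = 0.0
    delta_rel: float = 0.01
    sync_threshold: float = 0.95
    disorder_threshold: float = 0.05
    seed: int | None = None

    @property
    def sample_stride(self) -> int:
        stride = int(round(self.sample_every / self.dt))
        return max(stride, 1)


@dataclass
class PointSummary:
    """Result of one simulation point."""

    g1_a: float
    g1_b: float
    label_a: str
    label_b: str
    m: np.ndarray
    omega: np.ndarray
    order: np.ndarray
    n_a: int
    snapshot_u: np.ndarray
    coherence: CoherenceResult
    params: FHNParameters
    config: RunConfig

    @property
    def omega_a_sorted(self) -> np.ndarray:
        return self.omega[self.order[: self.n_a]]

    @property
    def omega_b_sorted(self) -> np.ndarray:
        return self.omega[self.order[self.n_a :]]

    def node_table(self) -> pd.DataFrame:
        """Per-node table: (node, layer, m, omega, sorted_rank)."""
        n = self.omega.size
        rank = np.empty(n, dtype=int)
        rank[self.order[: self.n_a]] = np.arange(self.n_a)
        rank[self.order[self.n_a :]] = np.arange(n - self.n_a)
        return pd.DataFrame(
            {
                "node": np.arange(n),
                "layer": ["A"] * self.n_a + ["B"] * (n - self.n_a),
                "m": self.m,
                "omega": self.omega,
                "sorted_rank": rank,
            }
        )

    def coherence_table(self) -> pd.DataFrame:
        """Coherence series table: (time, g0_a, g0_b), post-transient times."""
        n_samp = self.coherence.g0_a.size
        times = self.config.t_trans + np.arange(n_samp) * self.config.sample_every
        return pd.DataFrame(
            {"time": times, "g0_a": self.coherence.g0_a, "g0_b": self.coherence.g0_b}
        )


def run_point(
    net: LayeredNetwork,
    params: FHNParameters,
    config: RunConfig = RunConfig(),
    initial: SystemState | None = None,
) -> PointSummary:
    """Integrate one parameter point and compute all diagnostics.

    Fully determined by ``config.seed`` (and ``initial`` when given).
    """
    if initial is None:
        initial = random_initial_conditions(net, config.seed)
    # transient: keep only the final state
    state = initial
    if config.t_trans > 0:
        n_steps = int(round(config.t_trans / config.dt))
        trans = integrate(
            state, params, net, config.t_trans, config.dt, sample_stride=n_steps
        )
        state = trans.final_state
    traj = integrate(
        state, params, net, config.t_measure, config.dt, config.sample_stride
    )
    profile = velocity_profile(
        traj.u, config.t_measure, net.n_a, config.firing_threshold
    )
    coh = coherence_from_samples(
        traj.u,
        profile.order,
        net.n_a,
        config.delta_rel,
        config.sync_threshold,
        config.disorder_threshold,
    )
    return PointSummary(
        g1_a=coh.g1_a,
        g1_b=coh.g1_b,
        label_a=coh.label_a,
        label_b=coh.label_b,
        m=profile.m,
        omega=profile.omega,
        order=profile.order,
        n_a=net.n_a,
        snapshot_u=traj.u[-1].copy(),
        coherence=coh,
        params=params,
        config=config,
    )


@dataclass
class SweepSpec:
    """A 1- or 2-axis grid over dynamics/topology parameters.

    ``axis1``/``axis2`` name a sweepable parameter (lambda_in, lambda_out,
    alpha or l_out) with its grid values; ``axis2`` may be None.  ``fixed``
    holds the remaining :class:`FHNParameters` fields.  When an axis is
    ``l_out`` the inter-layer links are regenerated per point from the
    spec's base network's intra-layers, nested by default.
    """

    net: LayeredNetwork
    axis1: str
    values1: Sequence
    axis2: str | None = None
    values2: Sequence = ()
    fixed: Mapping = field(default_factory=dict)
    config: RunConfig = RunConfig()
    replicates: int = 1
    nested_interlayer: bool = True
    seed: int | None = None

    def __post_init__(self):
        axes = [self.axis1] + ([self.axis2] if self.axis2 else [])
        for ax in axes:
            if ax not in SWEEPABLE:
                raise ValueError(f"axis {ax!r} not in {SWEEPABLE}")
        if self.axis2 == self.axis1:
            raise ValueError("axes must be distinct")
        if len(self.values1) < 1 or (self.axis2 and len(self.values2) < 1):
            raise ValueError("grid sizes must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PhaseDiagram:
    """Grid of g1 values and labels per layer, plus raw per-run rows."""

    axis1: str
    values1: np.ndarray
    axis2: str | None
    values2: np.ndarray
    g1_a: np.ndarray
    g1_b: np.ndarray
    label_a: np.ndarray
    label_b: np.ndarray
    table: pd.DataFrame
    provenance: dict


_CSV_FIELDS = [
    "i1",
    "i2",
    "replicate",
    "axis1_value",
    "axis2_value",
    "g1_a",
    "g1_b",
    "label_a",
    "label_b",
    "failed",
    "seed",
]


def _point_inputs(spec: SweepSpec, v1, v2, pair_order, link_seed):
    """Network and parameters for one grid point."""
    point = dict(spec.fixed)
    point[spec.axis1] = v1
    if spec.axis2:
        point[spec.axis2] = v2
    if "l_out" in point:
        l_out = int(point.pop("l_out"))
        net = add_interlayer_links(
            spec.net.adj_a,
            spec.net.adj_b,
            l_out,
            seed=link_seed,
            pair_order=pair_order,
        )
    else:
        net = spec.net
    return net, FHNParameters(**point)


def run_sweep(
    spec: SweepSpec, out_path=None, progress: bool = False
) -> PhaseDiagram:
    """Run (or resume) a sweep and aggregate it into a :class:`PhaseDiagram`.

    With ``out_path`` given, each completed run is appended to a CSV
    immediately; on restart, runs already present in the file are skipped,
    so an interrupted sweep resumes to the identical result.  Failed points
    are recorded with ``failed = 1`` and NaN coherence, and the sweep
    continues.
    """
    values1 = list(spec.values1)
    values2 = list(spec.values2) if spec.axis2 else [None]
    ss = np.random.SeedSequence(spec.seed)
    # independent streams: one for the inter-link permutation, one per run
    link_ss, run_ss = ss.spawn(2)
    pair_order = None
    if spec.axis1 == "l_out" or spec.axis2 == "l_out" or "l_out" in spec.fixed:
        if spec.nested_interlayer:
            pair_order = interlayer_pair_permutation(
                spec.net.n_a, spec.net.n_b, seed=link_ss
            )

    n1, n2, reps = len(values1), len(values2), spec.replicates
    run_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in run_ss.spawn(n1 * n2 * reps)
    ]

    done: dict[tuple[int, int, int], dict] = {}
    if out_path is not None and Path(out_path).exists():
        with open(out_path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (int(row["i1"]), int(row["i2"]), int(row["replicate"]))
                done[key] = row

    writer = None
    fh = None
    if out_path is not None:
        exists = Path(out_path).exists()
        fh = open(out_path, "a", newline="")
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        if not exists:
            writer.writeheader()
            fh.flush()

    rows = []
    try:
        for (i1, v1), (i2, v2) in itertools.product(
            enumerate(values1), enumerate(values2)
        ):
            for r in range(reps):
                key = (i1, i2, r)
                if key in done:
                    rows.append(done[key])
                    continue
                seed = run_seeds[(i1 * n2 + i2) * reps + r]
                # inter-link seed: deterministic per point when not nested
                link_seed = seed + 1 if pair_order is None else None
                row = {
                    "i1": i1,
                    "i2": i2,
                    "replicate": r,
                    "axis1_value": v1,
                    "axis2_value": v2 if v2 is not None else "",
                    "seed": seed,
                }
                try:
                    net, params = _point_inputs(spec, v1, v2, pair_order, link_seed)
                    summary = run_point(
                        net, params, replace(spec.config, seed=seed)
                    )
                    row.update(
                        g1_a=summary.g1_a,
                        g1_b=summary.g1_b,
                        label_a=summary.label_a,
                        label_b=summary.label_b,
                        failed=0,
                    )
                except Exception as exc:  # record and continue
                    row.update(
                        g1_a="nan",
                        g1_b="nan",
                        label_a="failed",
                        label_b="failed",
                        failed=1,
                    )
                    if progress:
                        print(f"point {key} failed: {exc}", flush=True)
                rows.append(row)
                if writer is not None:
                    writer.writerow(row)
                    fh.flush()
                if progress:
                    print(
                        f"[{spec.axis1}={v1}"
                        + (f", {spec.axis2}={v2}" if spec.axis2 else "")
                        + f", rep {r}] g1_a={row['g1_a']}, g1_b={row['g1_b']}",
                        flush=True,
                    )
    finally:
        if fh is not None:
            fh.close()

    table = pd.DataFrame(rows)
    for col in ("i1", "i2", "replicate", "failed"):
        table[col] = table[col].astype(int)
    for col in ("g1_a", "g1_b"):
        table[col] = pd.to_numeric(table[col], errors="coerce")

    from .observables import classify_state

    g1_a = np.full((n1, n2), np.nan)
    g1_b = np.full((n1, n2), np.nan)
    label_a = np.full((n1, n2), "failed", dtype=object)
    label_b = np.full((n1, n2), "failed", dtype=object)
    grouped = table[table["failed"] == 0].groupby(["i1", "i2"])
    for (i1, i2), grp in grouped:
        g1_a[i1, i2] = grp["g1_a"].mean()
        g1_b[i1, i2] = grp["g1_b"].mean()
        label_a[i1, i2] = classify_state(
            g1_a[i1, i2],
            spec.config.sync_threshold,
            spec.config.disorder_threshold,
        )
        label_b[i1, i2] = classify_state(
            g1_b[i1, i2],
            spec.config.sync_threshold,
            spec.config.disorder_threshold,
        )
    return PhaseDiagram(
        axis1=spec.axis1,
        values1=np.asarray(values1),
        axis2=spec.axis2,
        values2=np.asarray(values2 if spec.axis2 else []),
        g1_a=g1_a,
        g1_b=g1_b,
        label_a=label_a,
        label_b=label_b,
        table=table,
        provenance={
            "seed": spec.seed,
            "replicates": reps,
            "fixed": dict(spec.fixed),
            "config": spec.config,
        },
    )


def regime_showcase(
    net: LayeredNetwork,
    scenario: str,
    config: RunConfig = RunConfig(),
    alpha: float = np.pi / 2 - 0.1,
) -> PointSummary:
    """Run one canonical coupling scenario and report its diagnostics.

    Scenarios map to (lambda_in, lambda_out) pairs at alpha = pi/2 - 0.1:
    disorder (0.1, 0.3), chimera (0.1, 1.8), unihemispheric (0.4, 3.5),
    sync (4.0, 3.5).  On synthetic networks the labels are reported as
    computed; which regime a given topology realizes depends on the
    network.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    lam_in, lam_out = SCENARIOS[scenario]
    params = FHNParameters(alpha=alpha, lambda_in=lam_in, lambda_out=lam_out)
    return run_point(net, params, config)
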