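"""Seed-reproducible generators for every analysis stage.

Three families of synthetic data:

- codon sequences: a duplication trio evolved codon-by-codon under GY94 as
  an explicit jump process (so every realized substitution is recorded in
  a truth ledger, letting parsimony mapping itself be audited), and
  multi-taxon alignments evolved by endpoint sampling under one-ratio or
  two-ratio branch models for selection-test calibration;
- trio event maps with optional hotspot windows of elevated event density,
  the direct input to hotspot-scan calibration and power studies;
- voltage-clamp trace families under the step, steady-state-inactivation
  and paired-pulse recovery protocols, built from Hodgkin-Huxley-style
  m^3 h kinetics with a persistent (non-inactivating) floor, linear leak,
  and additive Gaussian noise.

All generators are bit-reproducible from their (spec, seed) arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_selection import (
    CodonFrequencies,
    N_CODONS,
    gy94_rate_matrix,
    uniform_frequencies,
    _NONSYN,
    _SINGLE,
)
from .ephys_analysis import Sweep, VoltageClampTraceSet
from .parsimony_map import BRANCHES, BranchEventMap, Event
from .sequence_io import CodonAlignment, LabeledTree, Role, SENSE_CODONS


# --- trio event maps (hotspot-scan inputs) --------------------------------

def simulate_event_map(n_events: dict[Role, int] | tuple[int, int, int],
                       L: int,
                       windows: list[tuple[int, int, float, Role]] = (),
                       seed: int = 0) -> BranchEventMap:
    """Place events on trio branches, uniformly or with hotspot windows.

    ``windows`` entries are (start, end, multiplier, branch) with 1-based
    inclusive columns: within the window, that branch's per-column event
    probability is ``multiplier`` times the background. Events are drawn
    independently with replacement (collisions allowed), the same
    placement model as the scan's Monte-Carlo null.
    """
    if not isinstance(n_events, dict):
        n_events = dict(zip(BRANCHES, n_events))
    rng = np.random.default_rng(seed)
    emap = BranchEventMap(length=L)
    for b in BRANCHES:
        w = np.ones(L)
        for start, end, mult, wb in windows:
            if not (1 <= start <= end <= L):
                raise ValueError(f"window ({start}, {end}) outside 1..{L}")
            if mult < 1:
                raise ValueError("window multiplier must be >= 1")
            if Role(wb) is b:
                w[start - 1: end] *= mult
        if np.all(w == 1.0):
            # identical placement primitive to the scan's Monte-Carlo null
            cols = rng.integers(0, L, size=n_events[b]) + 1
        else:
            cols = rng.choice(L, size=n_events[b], replace=True,
                              p=w / w.sum()) + 1
        emap.events[b] = [Event(int(c), "substitution", "...")
                          for c in sorted(cols)]
    return emap


# --- codon-sequence simulation --------------------------------------------

@dataclass
class TrioSimSpec:
    """Conditions for jump-process simulation of a duplication trio.

    Branch lengths are expected substitutions per codon (under the
    branch's own omega, before any window multiplier); hotspot windows
    multiply the nonsynonymous rate within 1-based codon columns
    [start, end] on one branch.
    """

    n_codons: int
    branch_lengths: dict[Role, float]
    kappa: float = 2.0
    omega: dict[Role, float] = field(
        default_factory=lambda: {b: 0.2 for b in BRANCHES})
    windows: list[tuple[int, int, float, Role]] = field(default_factory=list)
    indel_rate: float = 0.0          # expected deletion events per branch/codon
    mean_indel_codons: float = 3.0
    freqs: CodonFrequencies | None = None
    seed: int = 0


def _window_mask(spec: TrioSimSpec, branch: Role) -> np.ndarray:
    mask = np.ones(spec.n_codons)
    for start, end, mult, wb in spec.windows:
        if not (1 <= start <= end <= spec.n_codons):
            raise ValueError(f"window ({start}, {end}) outside codon columns")
        if mult < 1:
            raise ValueError("window multiplier must be >= 1")
        if Role(wb) is branch:
            mask[start - 1: end] = mult
    return mask


def _evolve_site_jump(state: int, T: float, Q_base: np.ndarray,
                      mult: float, Q_mult: np.ndarray | None,
                      rng: np.random.Generator) -> tuple[int, list]:
    """CTMC jump simulation of one codon site for time T.

    Returns the final state and the list of (state_from, state_to) jumps.
    """
    Q = Q_base if mult == 1.0 else Q_mult
    jumps = []
    t = 0.0
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t > T:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        new = int(rng.choice(N_CODONS, p=probs))
        jumps.append((state, new))
        state = new
    return state, jumps


def simulate_codon_trio(spec: TrioSimSpec
                        ) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve a duplication trio from a common root, with a truth ledger.

    The root codon sequence is drawn from the equilibrium frequencies
    (uniform-nucleotide F3X4 by default); each branch evolves every site
    as an independent GY94 jump process with the branch's omega, the
    nonsynonymous rate multiplied inside that branch's hotspot windows.
    The ledger records every realized substitution (branch, codon column,
    syn/nonsyn, from/to codons) and deletion. Sequence ids are the role
    names.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.freqs if spec.freqs is not None else uniform_frequencies()
    root = rng.choice(N_CODONS, size=spec.n_codons, p=freqs.pi)
    ledger_rows = []
    seqs: dict[Role, np.ndarray] = {}
    deletions: dict[Role, np.ndarray] = {}
    for b in BRANCHES:
        Q = gy94_rate_matrix(spec.kappa, spec.omega[b], freqs)
        mask = _window_mask(spec, b)
        Q_mult_cache: dict[float, np.ndarray] = {}
        seq = root.copy()
        for site in range(spec.n_codons):
            m = float(mask[site])
            if m != 1.0 and m not in Q_mult_cache:
                Qm = Q.copy()
                np.fill_diagonal(Qm, 0.0)
                Qm[_NONSYN & _SINGLE] *= m
                np.fill_diagonal(Qm, -Qm.sum(axis=1))
                Q_mult_cache[m] = Qm
            final, jumps = _evolve_site_jump(
                int(seq[site]), spec.branch_lengths[b], Q,
                m, Q_mult_cache.get(m), rng)
            seq[site] = final
            for s_from, s_to in jumps:
                ledger_rows.append({
                    "branch": b.value, "column": site + 1,
                    "kind": "nonsyn" if _NONSYN[s_from, s_to] else "syn",
                    "from_codon": SENSE_CODONS[s_from],
                    "to_codon": SENSE_CODONS[s_to]})
        gap = np.zeros(spec.n_codons, dtype=bool)
        if spec.indel_rate > 0:
            n_dels = rng.poisson(spec.indel_rate * spec.n_codons)
            for _ in range(n_dels):
                start = int(rng.integers(0, spec.n_codons))
                length = 1 + int(rng.geometric(1.0 / spec.mean_indel_codons))
                gap[start: start + length] = True
                ledger_rows.append({
                    "branch": b.value, "column": start + 1, "kind": "indel",
                    "from_codon": "", "to_codon": ""})
        seqs[b] = seq
        deletions[b] = gap
    records = []
    for b in BRANCHES:
        chars = [SENSE_CODONS[c] if not deletions[b][i] else "---"
                 for i, c in enumerate(seqs[b])]
        records.append((b.value, "".join(chars)))
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["branch", "column", "kind", "from_codon", "to_codon"])
    return CodonAlignment(records), ledger


def simulate_multitaxon_codon(tree: LabeledTree, kappa: float,
                              omega: dict[str, float], n_codons: int,
                              seed: int = 0,
                              freqs: CodonFrequencies | None = None
                              ) -> CodonAlignment:
    """Evolve a codon alignment along a tree by endpoint sampling.

    ``omega`` maps branch classes ({"background"} or {"background",
    "foreground"}) to dN/dS; foreground branches are those flagged '#1'
    on the tree. The root sequence is drawn from the equilibrium
    frequencies; each branch applies the transition matrix exp(Q t).
    Records appear in leaf-iteration order of the tree.
    """
    from .codon_selection import _EigenQ

    rng = np.random.default_rng(seed)
    freqs = freqs if freqs is not None else uniform_frequencies()
    eig = {
        cls: _EigenQ(gy94_rate_matrix(kappa, w, freqs), freqs.pi)
        for cls, w in omega.items()
    }
    root_seq = rng.choice(N_CODONS, size=n_codons, p=freqs.pi)
    states = {tree.tree.seed_node: root_seq}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        cls = ("foreground"
               if getattr(node.edge, "foreground", False) and
               "foreground" in omega else "background")
        t = node.edge.length or 0.0
        parent = states[node.parent_node]
        if t == 0.0:
            states[node] = parent.copy()
            continue
        P = eig[cls].expm(t)
        cum = np.cumsum(P, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(n_codons)
        child = np.empty(n_codons, dtype=np.int64)
        for c in range(N_CODONS):
            sel = parent == c
            if sel.any():
                child[sel] = np.searchsorted(cum[c], u[sel])
        states[node] = child
    records = []
    for leaf in tree.tree.leaf_node_iter():
        seq = "".join(SENSE_CODONS[c] for c in states[leaf])
        records.append((leaf.taxon.label, seq))
    return CodonAlignment(records)


# --- voltage-clamp traces -------------------------------------------------

@dataclass
class TraceSimSpec:
    """Conditions for synthetic voltage-clamp families.

    Kinetics: activation gate m relaxes toward m_inf(V) with tau_m and
    enters the conductance cubed; inactivation gate h relaxes toward
    h_inf(V) with a voltage-dependent time constant (tau_h when
    depolarized, tau_rec at strongly hyperpolarized recovery potentials,
    tau_slow in between). Channel current:

        i(t) = g_max * m(t)^3 * [(1 - p) h(t) + p] * (V - E_rev)

    plus ohmic leak g_leak * V and additive Gaussian noise. ``p`` is the
    persistent (non-inactivating) fraction of the conductance.
    """

    g_max: float = 0.02            # uS-scale conductance, arbitrary units
    e_rev_mv: float = 50.0
    act_v_half: float = -40.0      # activation midpoint of m_inf^3 (mV)
    act_k: float = 7.0
    inact_v_half: float = -70.0
    inact_k: float = 6.0
    tau_m_ms: float = 0.1
    tau_h_ms: float = 3.0
    tau_rec_ms: float = 2.0
    tau_slow_ms: float = 100.0
    persistent_fraction: float = 0.0
    g_leak: float = 0.002
    leak_offset: float = 0.0
    noise_sd: float = 0.005
    sampling_hz: float = 50_000.0
    holding_mv: float = -120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistent_fraction <= 1.0:
            raise ValueError("persistent fraction must be in [0, 1]")
        for name in ("tau_m_ms", "tau_h_ms", "tau_rec_ms", "tau_slow_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # steady-state curves; m_inf is chosen so that m_inf^3 is exactly the
    # target Boltzmann, making fitted G-V parameters comparable to inputs
    def m_inf(self, v: float) -> float:
        return (1.0 / (1.0 + np.exp((self.act_v_half - v) / self.act_k))) ** (1 / 3)

    def h_inf(self, v: float) -> float:
        return 1.0 / (1.0 + np.exp((v - self.inact_v_half) / self.inact_k))

    def tau_h_of(self, v: float) -> float:
        if v >= -60.0:
            return self.tau_h_ms
        if v <= -110.0:
            return self.tau_rec_ms
        return self.tau_slow_ms


def _simulate_sweep(spec: TraceSimSpec,
                    segments: list[tuple[float, float]],
                    rng: np.random.Generator) -> np.ndarray:
    """Sample one sweep's current over piecewise-constant segments."""
    m = spec.m_inf(spec.holding_mv)
    h = spec.h_inf(spec.holding_mv)
    chunks = []
    for v, dur_ms in segments:
        n = int(round(dur_ms * spec.sampling_hz / 1000.0))
        t = (np.arange(n) + 1.0) / spec.sampling_hz * 1000.0
        m_inf, h_inf = spec.m_inf(v), spec.h_inf(v)
        tau_h = spec.tau_h_of(v)
        m_t = m_inf + (m - m_inf) * np.exp(-t / spec.tau_m_ms)
        h_t = h_inf + (h - h_inf) * np.exp(-t / tau_h)
        p = spec.persistent_fraction
        i = (spec.g_max * m_t ** 3 * ((1 - p) * h_t + p) * (v - spec.e_rev_mv)
             + spec.g_leak * v + spec.leak_offset)
        chunks.append(i)
        m, h = float(m_t[-1]), float(h_t[-1])
    out = np.concatenate(chunks)
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return out


def simulate_traces(spec: TraceSimSpec, protocol: str = "step",
                    step_voltages: np.ndarray | None = None,
                    conditioning_voltages: np.ndarray | None = None,
                    intervals_ms: np.ndarray | None = None,
                    pulse_ms: float = 30.0) -> VoltageClampTraceSet:
    """Simulate a voltage-clamp trace family.

    - ``step``: 5 ms at holding, ``pulse_ms`` at each step voltage
      (default -115..+35 mV in 5-mV increments, the hyperpolarized steps
      providing channel-free points for the leak fit), 5 ms tail;
    - ``ssi``: the last 2 ms of a long conditioning pulse (h fully relaxed
      to h_inf of the conditioning voltage), 1 ms at -100 mV, then a 20-ms
      test pulse to -20 mV;
    - ``recovery``: 2 ms at holding, a 20-ms conditioning pulse to -20 mV,
      a recovery interval at holding, and an identical test pulse.
    """
    rng = np.random.default_rng(spec.seed)
    sweeps = []
    if protocol == "step":
        if step_voltages is None:
            step_voltages = np.arange(-115.0, 36.0, 5.0)
        for i, v in enumerate(step_voltages):
            segs = [(spec.holding_mv, 5.0), (float(v), pulse_ms),
                    (spec.holding_mv, 5.0)]
            sweeps.append(Sweep(sweep_id=f"step_{i:03d}", segments=segs,
                                current=_simulate_sweep(spec, segs, rng),
                                voltage=float(v)))
        meta = {"pulse_segment": 1, "pulse_ms": pulse_ms}
    elif protocol == "ssi":
        if conditioning_voltages is None:
            conditioning_voltages = np.arange(-120.0, -14.0, 5.0)
        for i, vc in enumerate(conditioning_voltages):
            segs = [(float(vc), 2.0), (-100.0, 1.0), (-20.0, 20.0)]
            # conditioning (500 ms) fully relaxes h: start the stored
            # sweep with gates at their conditioning steady state
            sub = TraceSimSpec(**{**spec.__dict__, "holding_mv": float(vc),
                                  "noise_sd": 0.0, "seed": 0})
            cur = _simulate_sweep(sub, segs, rng)
            if spec.noise_sd > 0:
                cur = cur + rng.normal(0.0, spec.noise_sd, size=cur.shape)
            sweeps.append(Sweep(sweep_id=f"ssi_{i:03d}", segments=segs,
                                current=cur, voltage=float(vc)))
        meta = {"test_segment": 2, "test_mv": -20.0}
    elif protocol == "recovery":
        if intervals_ms is None:
            intervals_ms = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0,
                                     15.0, 20.0, 30.0])
        for i, dt in enumerate(intervals_ms):
            segs = [(spec.holding_mv, 2.0), (-20.0, 20.0),
                    (spec.holding_mv, float(dt)), (-20.0, 20.0)]
            sweeps.append(Sweep(sweep_id=f"rec_{i:03d}", segments=segs,
                                current=_simulate_sweep(spec, segs, rng),
                                voltage=-20.0, interval_ms=float(dt)))
        meta = {"cond_segment": 1, "test_segment": 3}
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return VoltageClampTraceSet(protocol=protocol,
                                sampling_hz=spec.sampling_hz,
                                holding_mv=spec.holding_mv, sweeps=sweeps,
                                meta=meta)


# --- expression tables ----------------------------------------------------

def simulate_expression_tables(gene_means: dict[str, float],
                               tissues: list[str], n_replicates: int,
                               dispersion: float = 0.3, seed: int = 0,
                               n_transfrags: int = 1, n_isoforms: int = 1
                               ) -> pd.DataFrame:
    """Log-normal isoform-level expression table.

    Each gene's isoform abundances are ``mean/(n_transfrags*n_isoforms) *
    exp(dispersion * Z)`` with Z standard normal, so zero dispersion
    reproduces the specified gene means exactly (median parameterization).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, mean in gene_means.items():
        per_iso = mean / (n_transfrags * n_isoforms)
        for tissue in tissues:
            for rep in range(1, n_replicates + 1):
                for tf in range(1, n_transfrags + 1):
                    for iso in range(1, n_isoforms + 1):
                        noise = np.exp(dispersion * rng.standard_normal())
                        rows.append({
                            "gene": gene,
                            "transfrag": f"{gene}_g{tf}",
                            "isoform": f"{gene}_g{tf}_i{iso}",
                            "tissue": tissue, "replicate": rep,
                            "abundance": per_iso * noise})
    return pd.DataFrame(rows)
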