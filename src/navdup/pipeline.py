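"""End-to-end stage orchestration with config and provenance.

Each ``run_*`` function chains the library stages for one analysis,
writes tab-delimited/JSON outputs into the configured output directory,
and drops a ``provenance.json`` (package version, config, master seed,
config hash) sufficient to re-execute the run bit-identically. All
randomness derives from the single master seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_selection import fit_branch_model, lrt
from .ephys_analysis import (
    gv_curve,
    leak_subtract,
    persistent_percent,
    read_traces,
    recovery_fractions,
    ssi_curve,
)
from .hotspot_scan import BRANCHES, scan
from .parsimony_map import TrioAlignment, assign_events, event_table
from .quant_utils import (
    aggregate_gene_expression,
    ddcq_fold_change,
    scale_by_total_channel_expression,
)
from .sequence_io import ProteinAlignment, read_fasta, read_newick

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated configuration for the pipeline stages.

    Scan defaults are the analysis' standard settings: kernel bandwidth
    h = 15 residues, 10,000 null simulations, 99th-percentile threshold.
    """

    outdir: str = "navdup_out"
    seed: int = 0
    # scan
    trio_fasta: str | None = None
    roles: dict[str, str] = field(default_factory=dict)
    indel_mode: str = "per_run"
    h: float = 15.0
    n_sim: int = 10_000
    percentile: float = 99.0
    eps: float = 1e-8
    statistic: str = "max"
    # selection
    codon_fasta: str | None = None
    tree: str | None = None
    n_starts: int = 3
    drop_gap_columns: bool = False
    fix_branch_lengths: bool = False
    # ephys
    traces: list[dict] = field(default_factory=list)
    reversal_mv: float = 50.0
    pulse_ms: float = 30.0
    window_ms: float = 0.5
    leak_below_mv: float = -105.0
    # quant
    expression_tsv: str | None = None
    aggregation_mode: str = "sum_isoforms_then_mean"
    gene_set: list[str] = field(default_factory=list)
    cq_tsv: str | None = None
    calibrator: str | None = None

    def __post_init__(self) -> None:
        if self.h <= 0 or self.n_sim < 1 or not (0 < self.percentile < 100):
            raise ConfigError("invalid scan parameters (h, n_sim, percentile)")
        if self.statistic not in ("max", "pointwise"):
            raise ConfigError(f"unknown scan statistic {self.statistic!r}")
        if self.indel_mode not in ("per_run", "per_column"):
            raise ConfigError(f"unknown indel_mode {self.indel_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def substream_seed(master: int, name: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([master, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_provenance(config: RunConfig, outdir: Path, stage: str) -> None:
    prov = {
        "stage": stage,
        "navdup_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
    }
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1))


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_scan(config: RunConfig):
    """assign_events -> densities -> Monte-Carlo null -> hotspot calls."""
    if not config.trio_fasta or not config.roles:
        raise ConfigError("scan requires trio_fasta and a roles mapping")
    aln = read_fasta(config.trio_fasta, alphabet="protein")
    if not isinstance(aln, ProteinAlignment):
        raise ConfigError("scan input must be a protein alignment")
    trio = TrioAlignment(aln.with_roles(config.roles))
    emap = assign_events(trio, indel_mode=config.indel_mode)
    out = _outdir(config)
    event_table(emap, out / "events.tsv")
    result = scan(emap, h=config.h, eps=config.eps, n_sim=config.n_sim,
                  seed=substream_seed(config.seed, "scan-null"),
                  percentile=config.percentile, statistic=config.statistic)
    dens = pd.DataFrame({"column": np.arange(1, emap.length + 1)})
    for b in BRANCHES:
        dens[f"d_{b.value}"] = result.profiles[b].values
        dens[f"r_{b.value}"] = result.relative[b].values
    dens.to_csv(out / "density.tsv", sep="\t", index=False)
    thresholds = {
        b.value: result.null.thresholds[b] for b in BRANCHES}
    (out / "thresholds.json").write_text(json.dumps({
        "thresholds": thresholds, "n_sim": result.null.n_sim,
        "percentile": result.null.percentile, "seed": result.null.seed},
        indent=1))
    rows = [
        {"branch": h.branch.value, "start": h.start, "end": h.end,
         "peak_column": h.peak_x, "peak_relative_density": h.peak_r,
         "fold_over_threshold": h.fold_over_threshold}
        for b in BRANCHES for h in result.hotspots[b]
    ]
    pd.DataFrame(rows, columns=["branch", "start", "end", "peak_column",
                                "peak_relative_density",
                                "fold_over_threshold"]
                 ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
    _write_provenance(config, out, "scan")
    return result


def run_selection(config: RunConfig):
    """One-ratio and two-ratio branch-model fits plus the LRT."""
    if not config.codon_fasta or not config.tree:
        raise ConfigError("selection requires codon_fasta and tree")
    aln = read_fasta(config.codon_fasta, alphabet="codon")
    tree = read_newick(config.tree)
    tree.validate_for_two_ratio()
    kwargs = dict(n_starts=config.n_starts,
                  drop_gap_columns=config.drop_gap_columns,
                  fix_branch_lengths=config.fix_branch_lengths,
                  seed=substream_seed(config.seed, "selection-fit"))
    fit0 = fit_branch_model(aln, tree, model="one_ratio", **kwargs)
    fit1 = fit_branch_model(aln, tree, model="two_ratio", **kwargs)
    test = lrt(fit0, fit1, df=1)
    out = _outdir(config)
    fits = {}
    for name, fit in (("one_ratio", fit0), ("two_ratio", fit1)):
        fits[name] = {
            "lnl": fit.lnl, "kappa": fit.params.kappa,
            "omega": fit.params.omega,
            "branch_lengths": dict(zip(fit.edge_labels,
                                       fit.params.branch_lengths.tolist())),
            "converged": fit.converged,
        }
    (out / "fit.json").write_text(json.dumps(fits, indent=1))
    pd.DataFrame([{
        "lnl_one_ratio": test.lnl_null, "lnl_two_ratio": test.lnl_alt,
        "two_delta_lnl": test.statistic, "df": test.df,
        "p_value": test.p_value,
    }]).to_csv(out / "lrt.tsv", sep="\t", index=False)
    _write_provenance(config, out, "selection")
    return fit0, fit1, test


def run_ephys(config: RunConfig):
    """Leak subtraction, %I_NAP, Boltzmann fits, recovery fractions."""
    if not config.traces:
        raise ConfigError(
            "ephys requires traces: a list of {csv, json} family entries")
    out = _outdir(config)
    families = {}
    for entry in config.traces:
        try:
            ts = read_traces(entry["csv"], entry["json"])
        except FileNotFoundError as exc:
            raise ConfigError(f"missing trace file: {exc}") from exc
        families[ts.protocol] = ts
    results = {}
    leak = None
    if "step" in families:
        corrected, leak = leak_subtract(families["step"],
                                        leak_below_mv=config.leak_below_mv)
        pc = persistent_percent(corrected, pulse_ms=config.pulse_ms,
                                window_ms=config.window_ms)
        pc.table.to_csv(out / "persistent_current.tsv", sep="\t", index=False)
        gv = gv_curve(corrected, reversal_mv=config.reversal_mv)
        results["persistent"] = pc
        results["gv"] = gv
    if "ssi" in families:
        corrected, _ = leak_subtract(families["ssi"],
                                     leak_below_mv=config.leak_below_mv,
                                     params=leak)
        results["ssi"] = ssi_curve(corrected)
    if "recovery" in families:
        if leak is None:
            raise ConfigError("recovery analysis needs a step family in the "
                              "same run to estimate leak")
        corrected, _ = leak_subtract(families["recovery"], params=leak)
        rec = recovery_fractions(corrected)
        rec.table.to_csv(out / "recovery.tsv", sep="\t", index=False)
        results["recovery"] = rec
    fits = {}
    for name in ("gv", "ssi"):
        if name in results:
            f = results[name]
            fits[name] = {"v_half": f.v_half, "k": f.k,
                          "pedestal": f.pedestal, "amplitude": f.amplitude,
                          "converged": f.converged}
    if fits:
        (out / "boltzmann_fits.json").write_text(json.dumps(fits, indent=1))
    _write_provenance(config, out, "ephys")
    return results


def run_quant(config: RunConfig):
    """Expression aggregation + channel-share scaling, and/or ddCq."""
    out = _outdir(config)
    results = {}
    if config.expression_tsv:
        table = pd.read_csv(config.expression_tsv, sep="\t")
        agg = aggregate_gene_expression(table, mode=config.aggregation_mode)
        agg.to_csv(out / "gene_expression.tsv", sep="\t", index=False)
        results["gene_expression"] = agg
        if config.gene_set:
            shares = scale_by_total_channel_expression(agg, config.gene_set)
            shares.to_csv(out / "channel_shares.tsv", sep="\t", index=False)
            results["shares"] = shares
    if config.cq_tsv:
        if not config.calibrator:
            raise ConfigError("ddCq requires a calibrator sample")
        cq = pd.read_csv(config.cq_tsv, sep="\t")
        folds = ddcq_fold_change(cq, calibrator=config.calibrator)
        folds.to_csv(out / "ddcq_fold_change.tsv", sep="\t", index=False)
        results["folds"] = folds
    if not results:
        raise ConfigError("quant requires expression_tsv and/or cq_tsv")
    _write_provenance(config, out, "quant")
    return results
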