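"""End-to-end orchestration: parse -> scale -> truncate -> summarize ->
signal screen -> group contrasts -> report.

Two entry points cover the two kinds of input.  ``run_full`` starts from
a manifest of PSMC output files plus a Newick tree and produces the
per-lineage statistics table itself; ``run_table_mode`` starts from an
existing statistics table in the same layout (e.g. the packaged thrush
table).  Both end with the same screen-then-contrast logic: each of the
five variables (mean Ne, CV, degree, rate, deltaT) is first tested for
phylogenetic signal with the Abouheif-Moran permutation test, and the
one-tailed Mann-Whitney contrast of migrants vs residents is run only
for variables without signal (p > alpha), unless forced — variables with
signal are reported with their contrast marked "not_run".

The CV used in contrasts is recomputed as sd/mean from the table's mean
and SD columns when both are present: the ratio of the full-precision
columns, not a separately rounded CV column, is what downstream ranks
should see (rank statistics on a 2-decimal CV column are sensitive to
the rounding).
"""

from __future__ import annotations

import dataclasses
import platform
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

import paleopop
from paleopop.group_contrast import group_descriptives, mann_whitney_one_tailed
from paleopop.phylo_signal import abouheif_cmean
from paleopop.psmc_io import (
    read_manifest,
    read_newick,
    read_psmc,
    read_table,
    tip_labels,
    write_table,
)
from paleopop.trajectory_stats import (
    ScalingParams,
    replicate_envelope,
    scale_round,
    summarize,
    truncate_recent,
)

#: contrast variables, as (name, stats-table column) pairs
VARIABLES = (
    ("mean_ne", "mean_Ne_e4"),
    ("cv", "cv"),
    ("degree", "degree"),
    ("rate", "rate_per_yr"),
    ("deltaT", "deltaT_yr"),
)

REQUIRED_COLUMNS = ("taxon_id", "group", "mean_Ne_e4", "sd_Ne_e4", "degree",
                    "rate_per_yr", "deltaT_yr")


@dataclass
class RunConfig:
    manifest_path: str = ""
    tree_path: str = ""
    mu_per_site_year: float = 2.3e-9
    generation_years: float = 2.5
    bin_size: float = 100.0
    cutoff_years: float = 50_000.0
    peak_mode: str = "first_turning"
    epsilon: float = 0.05
    time_weighted: bool = False
    sd_ddof: int = 0
    n_permutations: int = 999
    signal_alpha: float = 0.05
    force_contrasts: bool = False
    round_index: int | None = None
    seed: int = 0
    output_dir: str = "paleopop_out"

    def scaling(self) -> ScalingParams:
        return ScalingParams(
            mu_per_site_year=self.mu_per_site_year,
            generation_years=self.generation_years,
            bin_size=self.bin_size,
        )


def _pick_round(raw, round_index: int | None):
    if round_index is None:
        return raw.last_round()
    for r in raw.rounds:
        if r.round_index == round_index:
            return r
    raise ValueError(f"{raw.source_label}: no round with index {round_index}")


def summarize_lineages(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Stages 1-4: per-lineage statistics table from the manifest's PSMC files."""
    manifest = read_manifest(config.manifest_path)
    base = Path(config.manifest_path).parent
    sp = config.scaling()
    rows, envelopes, notes = [], {}, []
    for entry in manifest.entries:
        raw = read_psmc(base / entry.psmc_path, entry.taxon_id)
        rnd = _pick_round(raw, config.round_index)
        traj = truncate_recent(scale_round(rnd, sp, taxon_id=entry.taxon_id),
                               config.cutoff_years)
        s = summarize(traj, peak_mode=config.peak_mode, epsilon=config.epsilon,
                      time_weighted=config.time_weighted, sd_ddof=config.sd_ddof)
        if s.rate is None:
            notes.append(f"{entry.taxon_id}: deltaT = 0, rate flagged missing")
        rows.append({
            "taxon_id": s.taxon_id,
            "group": entry.group,
            "mean_Ne_e4": s.mean_Ne / 1e4,
            "sd_Ne_e4": s.sd_Ne / 1e4,
            "cv": s.cv,
            "degree": s.degree,
            "rate_per_yr": np.nan if s.rate is None else s.rate,
            "deltaT_yr": s.deltaT,
            "mean_Ne": s.mean_Ne,
            "sd_Ne": s.sd_Ne,
            "N_peak": s.N_peak,
            "N_trough": s.N_trough,
            "t_peak_yr": s.t_peak,
            "t_trough_yr": s.t_trough,
            "n_steps": s.n_steps_retained,
        })
        if entry.replicate_paths:
            reps = []
            for rp in entry.replicate_paths:
                rraw = read_psmc(base / rp, f"{entry.taxon_id}:{rp}")
                reps.append(truncate_recent(
                    scale_round(_pick_round(rraw, config.round_index), sp),
                    config.cutoff_years))
            grid = np.geomspace(config.cutoff_years, max(r.t_years[-1] for r in reps), 200)
            envelopes[entry.taxon_id] = pd.DataFrame(replicate_envelope(reps, grid))
    return pd.DataFrame(rows), {"envelopes": envelopes, "notes": notes}


def _contrast_values(stats: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-variable value series indexed by taxon_id (CV recomputed from sd/mean)."""
    df = stats.set_index("taxon_id")
    out = {}
    for name, col in VARIABLES:
        if name == "cv" and {"mean_Ne_e4", "sd_Ne_e4"} <= set(df.columns):
            out[name] = df["sd_Ne_e4"] / df["mean_Ne_e4"]
        elif col in df.columns:
            out[name] = df[col].astype(float)
        else:
            raise ValueError(f"statistics table missing column {col!r}")
    return out


def screen_and_contrast(stats: pd.DataFrame, tree: dendropy.Tree | None,
                        n_permutations: int = 999, seed: int = 0,
                        signal_alpha: float = 0.05,
                        force: bool = False) -> dict:
    """Stages 5-7: signal screen, conditional contrasts, group descriptives."""
    missing = [c for c in REQUIRED_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"statistics table missing column(s): {missing}")
    values = _contrast_values(stats)
    groups = stats.set_index("taxon_id")["group"]

    signal_rows, contrast_rows, results = [], [], {}
    rng_seeds = np.random.SeedSequence(seed).generate_state(len(VARIABLES))
    for i, (name, _) in enumerate(VARIABLES):
        v = values[name]
        sig_p = np.nan
        if tree is not None:
            finite = v[np.isfinite(v)]
            use_tree = tree
            if len(finite) < len(v):
                taxa = [t for t in tip_labels(tree) if t in set(finite.index)]
                use_tree = tree.extract_tree_with_taxa_labels(taxa)
            sr = abouheif_cmean(use_tree, dict(finite), n_permutations=n_permutations,
                                seed=int(rng_seeds[i] % (2**31)), variable=name)
            sig_p = sr.p_value
            signal_rows.append({"variable": name, "cmean": sr.cmean_observed,
                                "p": sr.p_value, "nperm": sr.n_permutations,
                                "seed": sr.seed})
        run_it = force or tree is None or sig_p > signal_alpha
        if run_it:
            cr = mann_whitney_one_tailed(v[groups == "migrant"],
                                         v[groups == "resident"], variable=name)
            results[name] = cr
            contrast_rows.append({
                "variable": name, "U": cr.U, "U_complement": cr.u_complement,
                "n1": cr.n_migrant, "n2": cr.n_resident, "p_exact": cr.p_value,
                "method": cr.method, "direction": cr.alternative,
                "signal_p": sig_p, "status": "tested",
            })
        else:
            contrast_rows.append({
                "variable": name, "U": np.nan, "U_complement": np.nan,
                "n1": int((groups == "migrant").sum()),
                "n2": int((groups == "resident").sum()),
                "p_exact": np.nan, "method": "", "direction": "",
                "signal_p": sig_p, "status": "not_run",
            })

    desc_rows = []
    for name, _ in VARIABLES:
        v = values[name]
        for d in group_descriptives(v.to_numpy(), groups.to_numpy()):
            desc_rows.append({"variable": name, "group": d.group, "mean": d.mean,
                              "sd": d.sd, "n": d.n})

    delta = values["deltaT"]
    summary = {
        "overall_mean_deltaT_yr": float(delta.mean()),
        "min_deltaT_yr": float(delta.min()),
        "max_deltaT_yr": float(delta.max()),
    }
    return {
        "signal": pd.DataFrame(signal_rows),
        "contrasts": pd.DataFrame(contrast_rows),
        "descriptives": pd.DataFrame(desc_rows),
        "results": results,
        "summary": summary,
    }


def _write_outputs(stats: pd.DataFrame, report: dict, config: RunConfig,
                   extra: dict | None = None) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(stats, out / "lineage_stats.tsv")
    if not report["signal"].empty:
        write_table(report["signal"], out / "signal.tsv")
    write_table(report["contrasts"], out / "contrasts.tsv")
    write_table(report["descriptives"], out / "group_descriptives.tsv")
    if extra and extra.get("envelopes"):
        env_dir = out / "envelopes"
        env_dir.mkdir(exist_ok=True)
        for taxon, df in extra["envelopes"].items():
            write_table(df, env_dir / f"{taxon}.tsv")
    lines = [f"paleopop {paleopop.__version__} (python {platform.python_version()})",
             "config:"]
    lines += [f"  {k} = {v}" for k, v in dataclasses.asdict(config).items()]
    for k, v in report["summary"].items():
        lines.append(f"{k} = {v:.6g}")
    for note in (extra or {}).get("notes", []):
        lines.append(f"note: {note}")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def run_full(config: RunConfig) -> dict:
    """Full pipeline from a manifest of PSMC files and a Newick tree.

    Writes the per-lineage statistics, signal, contrasts and group
    descriptive TSVs plus a log into ``config.output_dir`` and returns
    the report dictionary.
    """
    tree = read_newick(config.tree_path) if config.tree_path else None
    stats, extra = summarize_lineages(config)
    if tree is not None:
        tips = set(tip_labels(tree))
        missing = sorted(set(stats["taxon_id"]) - tips)
        if missing:
            raise ValueError(f"manifest taxa absent from tree: {missing}")
    report = screen_and_contrast(stats, tree, n_permutations=config.n_permutations,
                                 seed=config.seed, signal_alpha=config.signal_alpha,
                                 force=config.force_contrasts)
    report["stats"] = stats
    _write_outputs(stats, report, config, extra)
    return report


def run_table_mode(stats: str | Path | pd.DataFrame,
                   tree: dendropy.Tree | str | Path | None = None,
                   config: RunConfig | None = None) -> dict:
    """Screen-and-contrast starting from an existing statistics table.

    ``stats`` is a TSV path or DataFrame in the lineage-statistics
    layout (taxon_id, group, mean_Ne_e4, sd_Ne_e4[, cv], degree,
    rate_per_yr, deltaT_yr).
    """
    config = config or RunConfig()
    if not isinstance(stats, pd.DataFrame):
        stats = read_table(stats)
    if tree is not None and not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    report = screen_and_contrast(stats, tree, n_permutations=config.n_permutations,
                                 seed=config.seed, signal_alpha=config.signal_alpha,
                                 force=config.force_contrasts)
    report["stats"] = stats
    if config.output_dir:
        _write_outputs(stats, report, config)
    return report
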