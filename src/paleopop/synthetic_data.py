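"""Synthetic demographic cohorts with migrant-like and resident-like archetypes.

Trajectories are generated directly as piecewise-constant Ne step
functions on a log-spaced time grid and converted to PSMC's coalescent
scaling on emission — no sequence simulation or HMM inference is
involved, so everything is deterministic given a seed and desk-scale.

An archetype has four phases, oldest to most recent:

1. origin at ``origin_time`` years before present with size ``origin_Ne``
   (the trajectory's trough / "PSMC inception");
2. log-linear growth to ``peak_Ne`` over ``growth_duration`` years (the
   target deltaT);
3. a plateau modulated by a glacial-cycle-like sinusoid (period default
   100 kyr) riding on a gentle secular decline, so the historic maximum
   sits at the end of the growth phase;
4. a recent decline of relative magnitude ``recent_decline``, echoing
   the common pattern of present-day sizes sitting below the historic
   peak.

Multiplicative lognormal noise on the relative sizes (emulating PSMC
estimation wobble across bootstrap replicates) is applied only when a
trajectory is emitted as a PSMC-format file.

The default migrant archetype has a long growth phase, high peak and
high variability; the resident archetype a short growth phase, low peak
and low variability — mirroring the contrast the pipeline is built to
detect (8 migrant vs 6 resident lineages by default).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from paleopop.psmc_io import ManifestEntry, SampleManifest, write_manifest, write_table
from paleopop.trajectory_stats import DemographicTrajectory, ScalingParams

#: relative decay across the post-peak plateau: real cohorts' recent sizes sit
#: well below the historic peak, and the decay keeps the historic maximum
#: unique on the discrete grid (cycle tops would otherwise re-touch the peak)
_PLATEAU_DECAY = 0.3


@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of one synthetic demographic archetype (units: years, individuals)."""

    origin_time: float = 4.0e6
    origin_Ne: float = 1.0e4
    growth_duration: float = 3.0e6
    peak_Ne: float = 8.0e5
    oscillation_period: float = 1.0e5
    oscillation_amplitude: float = 0.1
    recent_decline: float = 0.5
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.origin_Ne > 0 and self.peak_Ne > 0):
            raise ValueError("origin_Ne and peak_Ne must be positive")
        if not (0 < self.growth_duration < self.origin_time):
            raise ValueError("growth_duration must be positive and < origin_time")
        if not (0 <= self.oscillation_amplitude < 1):
            raise ValueError("oscillation_amplitude must be in [0, 1)")
        if not (0 <= self.recent_decline < 1):
            raise ValueError("recent_decline must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def migrant_archetype(**overrides) -> ArchetypeParams:
    """Long growth phase, high peak, high variability."""
    return replace(ArchetypeParams(), **overrides)


def resident_archetype(**overrides) -> ArchetypeParams:
    """Short growth phase, low peak, low variability."""
    base = ArchetypeParams(
        origin_time=2.0e6,
        origin_Ne=1.0e4,
        growth_duration=1.5e6,
        peak_Ne=2.0e5,
        oscillation_amplitude=0.05,
        recent_decline=0.3,
    )
    return replace(base, **overrides)


def make_trajectory(p: ArchetypeParams, n_steps: int = 64,
                    t_min: float = 1.0e4, taxon_id: str = "") -> DemographicTrajectory:
    """Deterministic piecewise-constant Ne trajectory for one archetype.

    Steps sit on a log-spaced grid from ``t_min`` to ``origin_time``
    (plus a leading step at t = 0 for the present), 64 steps by default —
    comparable to a real PSMC discretization.  Noise is applied only at
    emission, never here.
    """
    if n_steps < 8:
        raise ValueError("n_steps too small for a meaningful trajectory")
    t = np.concatenate([[0.0], np.geomspace(t_min, p.origin_time, n_steps - 1)])
    peak_time = p.origin_time - p.growth_duration
    in_growth = (t >= peak_time) & (t <= p.origin_time)
    if in_growth.sum() < 2:
        raise ValueError(
            f"grid too coarse: only {in_growth.sum()} step(s) fall inside the "
            f"{p.growth_duration:g}-year growth phase"
        )

    log_o, log_p = math.log(p.origin_Ne), math.log(p.peak_Ne)
    ne = np.empty_like(t)
    # growth phase (oldest): log-linear origin_Ne -> peak_Ne
    frac = (p.origin_time - t[in_growth]) / p.growth_duration
    ne[in_growth] = np.exp(log_o + (log_p - log_o) * frac)
    # plateau: glacial-cycle sinusoid dipping below the peak, plus a slight
    # secular decay.  Each step carries the oscillation's AVERAGE over its
    # time interval (a step function cannot resolve sub-interval wiggles);
    # where intervals exceed the cycle period the average tends to the
    # mid-cycle value, so the coarse ancient grid does not alias the cycle.
    plateau = t < peak_time
    if plateau.any():
        idx = np.flatnonzero(plateau)
        age_lo = peak_time - np.minimum(t[idx + 1], peak_time)  # interval start (young edge)
        age_hi = peak_time - t[idx]
        w = 2.0 * math.pi / p.oscillation_period
        span = np.maximum(age_hi - age_lo, 1e-9)
        avg_cos = (np.sin(w * age_hi) - np.sin(w * age_lo)) / (w * span)
        mod = 1.0 - p.oscillation_amplitude * (0.5 - 0.5 * avg_cos)
        mod *= 1.0 - _PLATEAU_DECAY * age_hi / max(peak_time, 1.0)
        ne[plateau] = p.peak_Ne * mod
    # recent decline: log-time ramp over the most recent window
    if p.recent_decline > 0:
        d_start = min(10.0 * t_min, peak_time / 2.0)
        recent = t < d_start
        tt = np.maximum(t[recent], t_min / 10.0)
        ramp = (math.log(d_start) - np.log(tt)) / (math.log(d_start) - math.log(t_min / 10.0))
        ne[recent] *= 1.0 - p.recent_decline * np.clip(ramp, 0.0, 1.0)
    return DemographicTrajectory(t_years=t, ne=ne, taxon_id=taxon_id)


def emit_psmc(traj: DemographicTrajectory, sp: ScalingParams = ScalingParams(),
              noise_sigma: float = 0.0, seed: int | None = None,
              pattern: str = "1+1+1+1+25*2+4+6", round_index: int = 0) -> str:
    """Render a trajectory as a single-round PSMC-format text block.

    Inverse of the standard scaling: N0 is the most recent step's Ne,
    theta0 = 4 * N0 * mu_gen * s, t_k = t_years / (2 N0 g) and
    lambda_k = Ne_k / N0, the latter multiplied by lognormal noise
    exp(eps), eps ~ Normal(0, noise_sigma^2), when noise_sigma > 0.
    Numbers are printed with 17 significant digits so a noise-free
    emission parses back bit-exactly.
    """
    n0 = float(traj.ne[0])
    theta0 = 4.0 * n0 * sp.mu_per_generation * sp.bin_size
    rho0 = theta0 / 5.0  # plausible rho/theta ratio; not consumed downstream
    t_coal = traj.t_years / (2.0 * n0 * sp.generation_years)
    lam = traj.ne / n0
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        lam = lam * np.exp(rng.normal(0.0, noise_sigma, size=lam.shape))
    max_t = float(t_coal[-1]) * 1.05
    lines = [
        f"RD\t{round_index}",
        f"TR\t{theta0:.17g}\t{rho0:.17g}",
        f"MT\t{max_t:.17g}",
        f"PA\t{pattern}",
    ]
    for k, (tc, lk) in enumerate(zip(t_coal, lam)):
        lines.append(f"RS\t{k}\t{tc:.17g}\t{lk:.17g}\t0\t0\t0")
    lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic study cohort (default mirrors 8 migrants + 6 residents)."""

    n_migrant: int = 8
    n_resident: int = 6
    migrant_params: ArchetypeParams = field(default_factory=migrant_archetype)
    resident_params: ArchetypeParams = field(default_factory=resident_archetype)
    jitter_sigma: float = 0.3  # lognormal SD on sizes; half of it on durations
    birth_rate: float = 1.0  # Yule speciation rate for the cohort tree
    clustered: bool = True  # group labels concentrated in one clade vs random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_migrant + self.n_resident < 4:
            raise ValueError("cohort needs at least 4 lineages in total")


@dataclass
class Cohort:
    manifest: SampleManifest
    psmc_texts: dict[str, str]
    trajectories: dict[str, DemographicTrajectory]
    tree: dendropy.Tree
    true_params: pd.DataFrame


def _jitter(params: ArchetypeParams, rng: np.random.Generator,
            sigma: float, seed: int) -> ArchetypeParams:
    szf = math.exp(rng.normal(0.0, sigma))
    szf2 = math.exp(rng.normal(0.0, sigma))
    durf = math.exp(rng.normal(0.0, sigma / 2.0))
    origin = params.origin_time * math.exp(rng.normal(0.0, sigma / 2.0))
    growth = min(params.growth_duration * durf, 0.9 * origin)
    return replace(
        params,
        origin_time=origin,
        growth_duration=growth,
        origin_Ne=params.origin_Ne * szf2,
        peak_Ne=params.peak_Ne * szf,
        seed=seed,
    )


def _yule_tree(n_tips: int, birth_rate: float, seed: int) -> dendropy.Tree:
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    tree.is_rooted = True
    return tree


def _assign_groups(tree: dendropy.Tree, n_migrant: int, clustered: bool,
                   rng: np.random.Generator) -> None:
    """Relabel tips as migrant_XX / resident_XX, clustered in a clade or randomly."""
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    if clustered:
        # clade whose size is closest to n_migrant seeds the migrant set
        best, best_gap = None, n + 1
        for node in tree.preorder_internal_node_iter():
            size = len(node.leaf_nodes())
            if size < n and abs(size - n_migrant) < best_gap:
                best, best_gap = node, abs(size - n_migrant)
        clade = best.leaf_nodes() if best is not None else []
        mig = list(clade)[:n_migrant]
        rest = [lf for lf in leaves if lf not in set(mig)]
        rng.shuffle(rest)
        mig += rest[: n_migrant - len(mig)]
        mig_set = set(mig)
    else:
        order = list(leaves)
        rng.shuffle(order)
        mig_set = set(order[:n_migrant])
    im = ir = 0
    for leaf in leaves:
        if leaf in mig_set:
            im += 1
            leaf.taxon.label = f"migrant_{im:02d}"
        else:
            ir += 1
            leaf.taxon.label = f"resident_{ir:02d}"


def make_cohort(spec: CohortSpec = CohortSpec(), sp: ScalingParams = ScalingParams(),
                n_steps: int = 64) -> Cohort:
    """Generate a full synthetic cohort: tree, per-taxon PSMC texts, truth table.

    All randomness flows from ``spec.seed``; identical specs give
    identical cohorts (including file bytes).
    """
    rng = np.random.default_rng(spec.seed)
    tree = _yule_tree(spec.n_migrant + spec.n_resident, spec.birth_rate,
                      seed=int(rng.integers(2**31)))
    _assign_groups(tree, spec.n_migrant, spec.clustered, rng)

    entries, texts, trajs, truth = [], {}, {}, []
    for leaf in tree.leaf_node_iter():
        taxon = leaf.taxon.label
        group = "migrant" if taxon.startswith("migrant") else "resident"
        base = spec.migrant_params if group == "migrant" else spec.resident_params
        params = _jitter(base, rng, spec.jitter_sigma, seed=int(rng.integers(2**31)))
        traj = make_trajectory(params, n_steps=n_steps, taxon_id=taxon)
        texts[taxon] = emit_psmc(traj, sp, noise_sigma=params.noise_sigma,
                                 seed=params.seed)
        trajs[taxon] = traj
        entries.append(ManifestEntry(taxon_id=taxon, group=group,
                                     psmc_path=f"psmc/{taxon}.psmc"))
        truth.append({
            "taxon_id": taxon,
            "group": group,
            "origin_time": params.origin_time,
            "origin_Ne": params.origin_Ne,
            "growth_duration": params.growth_duration,
            "peak_Ne": params.peak_Ne,
            "noise_sigma": params.noise_sigma,
        })
    return Cohort(
        manifest=SampleManifest(entries=entries),
        psmc_texts=texts,
        trajectories=trajs,
        tree=tree,
        true_params=pd.DataFrame(truth),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort's PSMC files, manifest, Newick tree and truth table."""
    out = Path(out_dir)
    (out / "psmc").mkdir(parents=True, exist_ok=True)
    for taxon, text in cohort.psmc_texts.items():
        (out / "psmc" / f"{taxon}.psmc").write_text(text)
    write_manifest(cohort.manifest, out / "manifest.tsv")
    (out / "tree.nwk").write_text(cohort.tree.as_string(schema="newick"))
    write_table(cohort.true_params, out / "true_params.tsv")
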