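"""End-to-end orchestration: simulate -> quantify -> kinetics -> phasing -> report.

A run is described by a plain configuration mapping (usually loaded from
YAML); every stochastic stage records its seed, and a reproducibility
manifest (parameters, package version, SHA-256 of every output) is written
next to the outputs.  Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fragment_quant, genome_sites, kinetics, phasing, synthetic_data

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "mode": "in_vivo",                 # or "nuclei"
    "design": [0, 30, 60, 120, 240],   # minutes (in_vivo) or nM (nuclei)
    "n_cells": 300,
    "molecule_cells": 200,             # cells contributing fragments per point
    "genome": {"chrom_len": 60_000, "n_genes": 25, "motif": "GATC"},
    "kinetics": {"preset": "dam", "k_orf": 0.01, "f0": 0.0},
    "induction": {"half_time": 80.0, "sigma_cell": 0.5},
    "fragmentation": {
        "mean_length": 350.0, "recovery_lo": 100.0,
        "recovery_hi": 300.0, "terminal_loss_prob": 0.3,
    },
    "stages": {"fcut": True, "kinetics": True, "phasing": True},
    "smooth_bp": 21,
    "min_pairs": 1,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _kinetics_params(cfg: dict) -> synthetic_data.KineticsParams:
    kcfg = cfg["kinetics"]
    preset = kcfg.get("preset", "dam")
    if cfg["mode"] == "nuclei":
        table = synthetic_data.nuclei_plateau_preset(
            p_orf=kcfg.get("p_orf", 0.30), p_ndr=kcfg.get("p_ndr", 0.70)
        )
        return synthetic_data.KineticsParams(
            mode="nuclei", plateau=table, f0=kcfg.get("f0", 0.0),
            c0=kcfg.get("c0", 0.8),
        )
    k_orf = kcfg.get("k_orf", 0.01)
    table = (
        synthetic_data.cg_rate_preset(k_orf)
        if preset == "cg"
        else synthetic_data.dam_rate_preset(k_orf)
    )
    return synthetic_data.KineticsParams(mode="in_vivo", rate=table, f0=kcfg.get("f0", 0.0))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run all enabled stages; returns the manifest (also written as JSON)."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    timers: dict[str, float] = {}

    tic = time.time()
    model = synthetic_data.make_demo_model(
        seed,
        chrom_len=int(cfg["genome"]["chrom_len"]),
        n_genes=int(cfg["genome"]["n_genes"]),
        motif=cfg["genome"]["motif"],
    )
    genome_sites.write_sites_table(model.sites, out / "sites.tsv")
    model.pairs.to_csv(out / "site_gene_pairs.tsv", sep="\t", index=False)
    kin = _kinetics_params(cfg)
    ind = synthetic_data.InductionModel(**cfg["induction"])
    states = synthetic_data.simulate_states(
        model, kin, cfg["design"], int(cfg["n_cells"]), seed, induction=ind
    )
    truth = synthetic_data.ground_truth_table(states)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    timers["simulate"] = time.time() - tic

    fcut_tables: dict[float, pd.DataFrame] = {}
    if stages.get("fcut", True):
        tic = time.time()
        frag = synthetic_data.FragmentationParams(**cfg["fragmentation"])
        n_mol = min(int(cfg["molecule_cells"]), states.n_cells)
        for d, x in enumerate(states.design):
            frags = synthetic_data.fragmentize(
                states, model.chrom_sizes, frag, seed,
                design_index=d, cells=np.arange(n_mol),
            )
            synthetic_data.write_bedpe(frags, out / f"fragments_{x:g}.bedpe")
            stats = fragment_quant.quantify(model.sites, frags, model.chrom_sizes)
            fragment_quant.write_fcut_table(stats, out / f"fcut_{x:g}.tsv")
            fcut_tables[float(x)] = stats
        timers["fcut"] = time.time() - tic

    if stages.get("kinetics", True) and fcut_tables:
        tic = time.time()
        series = kinetics.group_series(fcut_tables, group_by="region_class")
        series.to_csv(out / "series.tsv", sep="\t", index=False)
        if kin.mode == "in_vivo":
            fits = {}
            for group, grp in series.groupby("group"):
                try:
                    fits[str(group)] = kinetics.fit_rate(grp["x"], grp["u"])
                except ValueError:
                    continue
            kinetics.fits_to_frame(fits).to_csv(out / "fits.tsv", sep="\t", index=False)
        else:
            fits = {
                str(group): kinetics.fit_plateau(grp["x"], grp["median_fcut"])
                for group, grp in series.groupby("group")
                if len(grp) >= 4
            }
            kinetics.fits_to_frame(fits).to_csv(out / "fits.tsv", sep="\t", index=False)
        timers["kinetics"] = time.time() - tic

    if stages.get("phasing", True) and fcut_tables and len(model.pairs):
        tic = time.time()
        x_last = float(states.design[-1])
        stats = fcut_tables[x_last]
        pairs = model.pairs.merge(
            stats[["chrom", "start", "fcut", "status"]], on=["chrom", "start"], how="inner"
        )
        pairs = pairs[pairs["status"].isin(fragment_quant.USABLE_STATUSES)]
        profile = phasing.dyad_profile(pairs)
        profile = phasing.smooth_profile(
            profile, w=int(cfg["smooth_bp"]), min_pairs=int(cfg["min_pairs"])
        )
        phasing.profile_table(profile).to_csv(out / "profile.tsv", sep="\t", index=False)
        timers["phasing"] = time.time() - tic

    manifest = {
        "version": __version__,
        "config": cfg,
        "seed": seed,
        "elapsed_s": round(time.time() - t0, 3),
        "stage_timers_s": {k: round(v, 3) for k, v in timers.items()},
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bedpe"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_report(artifact_dir, with_plots: bool = False) -> dict[str, Path]:
    """Summary tables (and optional figures) from a pipeline artifact directory.

    Produces a region rate/plateau table and, when phasing ran, a profile
    overlay table; regeneration is idempotent.
    """
    art = Path(artifact_dir)
    outputs: dict[str, Path] = {}
    fits_path = art / "fits.tsv"
    if not fits_path.exists():
        raise FileNotFoundError(f"missing kinetics output: {fits_path}")
    fits = pd.read_csv(fits_path, sep="\t")
    all_regions = list(genome_sites.REGION_CLASSES)
    table = pd.DataFrame({"group": all_regions}).merge(fits, on="group", how="left")
    missing = table[table["estimate"].isna()]["group"].tolist()
    if missing:
        import logging

        logging.getLogger(__name__).warning("no estimate for region(s): %s", missing)
    path = art / "report_regions.tsv"
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    outputs["regions"] = path

    profile_path = art / "profile.tsv"
    if profile_path.exists():
        outputs["profile"] = profile_path
        if with_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            profile = pd.read_csv(profile_path, sep="\t")
            fig, ax = plt.subplots(figsize=(7, 3))
            ax.plot(profile["offset"], profile["smoothed"], lw=1.2)
            ax.set_xlabel("distance from +1 dyad (bp)")
            ax.set_ylabel("fcut")
            fig.tight_layout()
            png = art / "report_profile.png"
            fig.savefig(png, dpi=120)
            plt.close(fig)
            outputs["profile_plot"] = png
    return outputs
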