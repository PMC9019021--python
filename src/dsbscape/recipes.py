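"""End-to-end recipes chaining the documented operations on synthetic data.

Each recipe generates its inputs with the forward models, runs the analysis,
writes TSV/BED/JSON outputs plus a manifest (parameters + seed + version)
under the run directory, and returns the headline numbers.  Outputs are a
pure function of the configuration, so replaying a manifest reproduces them
byte-identically.

Numeric defaults follow the study conventions they emulate: catalogs of 100
sites with the 80 best-cleaved retained, quantile groups of 20, enrichment
ratios over 4 kb (factor) / 1 kb (cleavage) windows with 20 extreme sites
per class, +/-5 kb windowed sums for track-track correlation, and the
< 100 kb tandem-duplication size filter.
"""

from __future__ import annotations

import json
import os
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd

from . import (
    assay_qpcr,
    cancer_sv,
    dsb_classify,
    dsb_signal,
    signal_io,
    synthetic,
)
from .genome import toy_genome

RECIPES = (
    "fig1b_heatmap",
    "fig1d_groups",
    "blm_high_low",
    "fig4e_correlation",
    "fig5ef_cancer",
    "assay_suite",
)

DEFAULTS: dict[str, dict] = {
    "fig1b_heatmap": dict(
        n_sites=100, top_n=80, window=100_000, bin=1_000, total_reads=200_000
    ),
    "fig1d_groups": dict(
        n_sites=100, top_n=80, n_groups=4, sum_window=5_000, bin=100,
        total_reads=200_000, coupling=1.0,
    ),
    "blm_high_low": dict(
        n_sites=100, top_n=80, signal_window=4_000, cleavage_window=1_000,
        n_extreme=20, planted_fold=5.0, bin=100, total_reads=200_000,
    ),
    "fig4e_correlation": dict(
        n_sites=100, top_n=80, window=10_000, bin=100, target_pearson=0.8,
        total_reads=200_000,
    ),
    "fig5ef_cancer": dict(
        n_donors=200, beta=(float(np.log(5)), 0.3, 0.3, float(np.log(2))),
        dispersion=10.0, max_size=100_000,
    ),
    "assay_suite": dict(efficiency=2.0, ct_at_unit=30.0),
}


def _write_manifest(outdir: str, name: str, config: dict, outputs: list[str]) -> None:
    manifest = {
        "recipe": name,
        "config": config,
        "outputs": sorted(outputs),
        "version": _pkg_version("dsbscape"),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _matrix_tsv(matrix: dsb_signal.SiteSignalMatrix, path: str) -> None:
    df = pd.DataFrame(
        matrix.values,
        index=[f"{s.contig}:{s.position}" for s in matrix.sites],
        columns=matrix.offsets,
    )
    df.to_csv(path, sep="\t", float_format="%.6g")


def _profile_tsv(offsets, values, path: str) -> None:
    pd.DataFrame({"offset_bp": offsets, "signal": values}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def _sites_and_tracks(cfg, seed, kernels, couplings=None, site_amplitudes=None):
    """Shared scaffold: catalog, top-N, one CPM track per named kernel."""
    genome = toy_genome()
    sites = synthetic.make_sites(genome, n_sites=cfg["n_sites"], seed=seed)
    top = dsb_classify.top_n_by_cleavage(sites, cfg["top_n"])
    tracks = {}
    for i, (name, kernel) in enumerate(kernels.items()):
        reads = synthetic.simulate_reads(
            sites,
            kernel,
            genome=genome,
            background_rate=1e-5,
            total_reads=cfg["total_reads"],
            seed=seed + 101 + i,
            site_amplitudes=None if site_amplitudes is None else site_amplitudes.get(name),
        )
        reads = signal_io.deduplicate(reads)
        raw = signal_io.coverage(reads, genome, bin_size=cfg["bin"])
        tracks[name] = signal_io.cpm_normalize(raw)
    return genome, sites, top, tracks


def run_recipe(name: str, config: dict | None = None, outdir: str = ".") -> dict:
    """Run one named end-to-end analysis; returns its headline results."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; choose from {RECIPES}")
    cfg = dict(DEFAULTS[name])
    cfg.update(config or {})
    cfg.setdefault("seed", 0)
    seed = int(cfg["seed"])
    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []
    results = globals()[f"_recipe_{name}"](cfg, seed, outdir, outputs)
    _write_manifest(outdir, name, cfg, outputs)
    with open(os.path.join(outdir, "results.json"), "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results


def _recipe_fig1b_heatmap(cfg, seed, outdir, outputs):
    kernels = {
        "factor": synthetic.FactorKernel(
            shape="exponential", decay_length_bp=2_000, amplitude=1.0
        ),
        "broad": synthetic.FactorKernel(
            shape="plateau_with_dip", plateau_halfwidth_bp=25_000,
            dip_halfwidth_bp=1_000, amplitude=1.0,
        ),
    }
    _, sites, top, tracks = _sites_and_tracks(cfg, seed, kernels)
    out = {}
    for name, track in tracks.items():
        mat = dsb_signal.site_matrix(track, top, cfg["window"], cfg["bin"])
        mat = dsb_signal.order_by_cleavage(mat)
        path = os.path.join(outdir, f"heatmap_{name}.tsv")
        _matrix_tsv(mat, path)
        outputs.append(f"heatmap_{name}.tsv")
        profile = dsb_signal.average_profile(mat)
        ppath = os.path.join(outdir, f"profile_{name}.tsv")
        _profile_tsv(mat.offsets, profile, ppath)
        outputs.append(f"profile_{name}.tsv")
        out[f"{name}_spread_width_bp"] = dsb_signal.spread_width(profile, cfg["bin"])
    out["n_sites"] = len(top)
    return out


def _recipe_fig1d_groups(cfg, seed, outdir, outputs):
    kernels = {
        "factor": synthetic.FactorKernel(
            shape="exponential", decay_length_bp=2_000, amplitude=1.0,
            transcription_coupling=cfg["coupling"],
        )
    }
    _, sites, top, tracks = _sites_and_tracks(cfg, seed, kernels)
    groups = dsb_classify.quantile_groups(top, "transcription_score", cfg["n_groups"])
    sums = {
        dsb_signal.genomic_key(s): dsb_signal.window_sum(
            tracks["factor"], s, cfg["sum_window"]
        )
        for s in top
    }
    rows = [
        {
            "site": f"{c}:{p}",
            "group": groups.labels[(c, p)],
            "window_sum": sums[(c, p)],
        }
        for (c, p) in sorted(sums)
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "group_sums.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    outputs.append("group_sums.tsv")
    by_group = {
        g: np.array([r["window_sum"] for r in rows if r["group"] == g])
        for g in range(cfg["n_groups"])
    }
    comp = dsb_classify.wilcoxon_ranksum(by_group[0], by_group[cfg["n_groups"] - 1])
    return {
        "group_sizes": [len(by_group[g]) for g in sorted(by_group)],
        "top_vs_bottom_U": comp.statistic,
        "top_vs_bottom_p": comp.p_value,
    }


def _recipe_blm_high_low(cfg, seed, outdir, outputs):
    genome = toy_genome()
    sites = synthetic.make_sites(genome, n_sites=cfg["n_sites"], seed=seed)
    top = dsb_classify.top_n_by_cleavage(sites, cfg["top_n"])
    rng = np.random.default_rng(seed + 7)
    planted = set(
        rng.choice(len(top), size=cfg["n_extreme"], replace=False).tolist()
    )
    # amplitudes index the full catalog; planting applies to top-N sites only
    amps = np.ones(len(sites))
    key_to_idx = {dsb_signal.genomic_key(s): i for i, s in enumerate(sites)}
    planted_keys = set()
    for j in planted:
        k = dsb_signal.genomic_key(top[j])
        amps[key_to_idx[k]] = cfg["planted_fold"]
        planted_keys.add(k)

    factor_kernel = synthetic.FactorKernel(
        shape="exponential", decay_length_bp=2_000, amplitude=1.0
    )
    bless_kernel = synthetic.FactorKernel(shape="point", amplitude=1.0)
    factor_reads = synthetic.simulate_reads(
        sites, factor_kernel, genome=genome, background_rate=1e-5,
        total_reads=cfg["total_reads"], seed=seed + 11, site_amplitudes=amps,
    )
    bless_reads = synthetic.simulate_reads(
        sites, bless_kernel, genome=genome, background_rate=1e-5,
        total_reads=cfg["total_reads"], seed=seed + 13,
    )
    factor = signal_io.cpm_normalize(
        signal_io.coverage(factor_reads, genome, cfg["bin"])
    )
    bless = signal_io.cpm_normalize(
        signal_io.coverage(bless_reads, genome, cfg["bin"])
    )
    cls = dsb_classify.ratio_classify(
        top, factor, bless,
        signal_window=cfg["signal_window"],
        cleavage_window=cfg["cleavage_window"],
        n_extreme=cfg["n_extreme"],
    )
    with open(os.path.join(outdir, "classes.bed"), "w") as fh:
        for s in top:
            k = dsb_signal.genomic_key(s)
            fh.write(
                f"{s.contig}\t{s.position}\t{s.position + 1}\t"
                f"{cls.labels[k]}\t{cls.scores[k]:.6g}\t+\n"
            )
    outputs.append("classes.bed")
    high = set(cls.sites_with_label("high"))
    return {
        "n_high": len(high),
        "n_low": len(cls.sites_with_label("low")),
        "planted_recovered": len(high & planted_keys),
    }


def _recipe_fig4e_correlation(cfg, seed, outdir, outputs):
    genome = toy_genome()
    sites = synthetic.make_sites(genome, n_sites=cfg["n_sites"], seed=seed)
    top = dsb_classify.top_n_by_cleavage(sites, cfg["top_n"])
    kernel = synthetic.FactorKernel(
        shape="exponential", decay_length_bp=2_000, amplitude=1.0
    )
    reads_a, reads_b = synthetic.simulate_correlated_tracks(
        top, kernel, cfg["target_pearson"], genome=genome,
        total_reads=cfg["total_reads"], seed=seed + 17,
    )
    track_a = signal_io.cpm_normalize(signal_io.coverage(reads_a, genome, cfg["bin"]))
    track_b = signal_io.cpm_normalize(signal_io.coverage(reads_b, genome, cfg["bin"]))
    xs = [dsb_signal.window_sum(track_a, s, cfg["window"]) for s in top]
    ys = [dsb_signal.window_sum(track_b, s, cfg["window"]) for s in top]
    pd.DataFrame(
        {
            "site": [f"{s.contig}:{s.position}" for s in top],
            "track_a": xs,
            "track_b": ys,
        }
    ).to_csv(
        os.path.join(outdir, "windowed_sums.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    outputs.append("windowed_sums.tsv")
    return {"pearson_r": dsb_signal.pearson(xs, ys), "n_sites": len(top)}


def _recipe_fig5ef_cancer(cfg, seed, outdir, outputs):
    expr_df, sv_df = synthetic.simulate_donors(
        n_donors=cfg["n_donors"], beta=tuple(cfg["beta"]),
        dispersion=cfg["dispersion"], seed=seed + 23,
    )
    expr_df.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t", index=False)
    sv_df.to_csv(os.path.join(outdir, "sv.tsv"), sep="\t", index=False)
    outputs += ["expression.tsv", "sv.tsv"]
    strat = cancer_sv.stratify(expr_df, "SETX", "POLD3")
    counts = cancer_sv.td_counts_per_donor(
        sv_df, strat.assignments["donor_id"], cfg["max_size"]
    )
    by_group = {
        g: counts[strat.donors_in(g)].to_numpy()
        for g in cancer_sv.GROUP_LABELS.values()
    }
    pairs = [
        ("A_high/B_high", "A_high/B_low"),
        ("A_low/B_high", "A_low/B_low"),
    ]
    comps = cancer_sv.compare_groups(by_group, pairs)
    fit = cancer_sv.nb_interaction(
        counts.to_numpy(),
        strat.assignments["A"].to_numpy(),
        strat.assignments["B"].to_numpy(),
    )
    report = {
        "group_sizes": {g: len(v) for g, v in by_group.items()},
        "beta": fit.beta.tolist(),
        "theta": fit.theta,
        "interaction_p": fit.interaction_p,
        "converged": fit.converged,
        "wilcoxon": {
            f"{a} vs {b}": comps[(a, b)].p_value for a, b in pairs
        },
    }
    with open(os.path.join(outdir, "nb_fit.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs.append("nb_fit.json")
    return {
        "interaction_beta": float(fit.beta[3]),
        "interaction_p": fit.interaction_p,
        "group_sizes": sorted(len(v) for v in by_group.values()),
    }


def _recipe_assay_suite(cfg, seed, outdir, outputs):
    e, c0 = cfg["efficiency"], cfg["ct_at_unit"]
    results = {}
    # ChIP percent-input: IP captured 2% of chromatin, input aliquot = 10%
    ct = synthetic.simulate_qpcr([0.02, 0.10], efficiency=e, ct_at_unit=c0)
    results["percent_input"] = assay_qpcr.percent_input(
        ct["ct"][0], ct["ct"][1], input_fraction=0.10, efficiency=e
    )
    # resection: planted dCt of 4.8 cycles at ~1 kb from the cut
    results["ssdna_percent"] = assay_qpcr.ssdna_percent(c0 + 4.8, c0, efficiency=e)
    # repair fidelity: second-round cleavage at half the calibrator level
    ct2 = synthetic.simulate_qpcr([0.5, 1.0, 1.0, 1.0], efficiency=e, ct_at_unit=c0)
    results["recleavage_fraction"] = assay_qpcr.cleavage_fraction(
        ct2["ct"][0], ct2["ct"][1], ct2["ct"][2], ct2["ct"][3], efficiency=e
    )
    # enrichment over an origin-of-replication reference, planted 4x
    ct3 = synthetic.simulate_qpcr([4.0, 1.0], efficiency=e, ct_at_unit=c0)
    results["edu_over_ori"] = assay_qpcr.relative_quantity(
        ct3["ct"][0], ct3["ct"][1], efficiency=e
    )
    summary = assay_qpcr.replicate_summary([2.0, 4.0, 6.0], name="demo")
    results["replicate_mean"] = summary.mean
    results["replicate_sem"] = summary.sem
    pd.DataFrame(
        sorted(results.items()), columns=["quantity", "value"]
    ).to_csv(
        os.path.join(outdir, "assays.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    outputs.append("assays.tsv")
    return results
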