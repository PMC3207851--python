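"""End-to-end orchestration: simulate -> QC -> map -> distortion ->
interference -> features -> scaling.

:class:`RunConfig` carries either simulation parameters (the default
configuration emulates the study design: two backcross populations of ~1,500
plants genotyped at 380 SNPs over the five Arabidopsis chromosomes) or paths
to existing tables.  :func:`run_all` produces a machine-readable report and,
optionally, the intermediate tables on disk.  All randomness flows from the
single master seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distortion as dst
from . import features as feat
from . import interference as itf
from . import mapping as mp
from . import scaling as sc
from . import simulate as sim
from .io import (
    CODE_A,
    CODE_H,
    write_genotype_matrix,
    write_interval_table,
    write_marker_map,
    flag_singletons,
)

__all__ = ["ChromosomeConfig", "RunConfig", "run_all", "default_config", "build_specs"]

log = logging.getLogger("heterochiasma")

REPORT_SCHEMA_VERSION = 1


@dataclass
class ChromosomeConfig:
    name: str
    physical_mb: float
    centromere_mb: float
    genetic_length_male: float  # Morgans (true simulated lengths)
    genetic_length_female: float
    nu_male: float
    nu_female: float
    n_markers: int
    map_knots_male: list | None = None  # optional (bp, Morgan) pairs
    map_knots_female: list | None = None


@dataclass
class RunConfig:
    """Pipeline configuration with the study's default thresholds.

    Defaults: BH level ``q = 0.05``, heterochromatin threshold 0.2,
    physical truncations 30% and 50% (15% / 25% per end), distortion bands
    at 2.33 standard errors, ``max_missing_frac = 0.1``.
    """

    chromosomes: list = field(default_factory=list)
    n_plants_male: int = 1505
    n_plants_female: int = 1507
    missing_rate: float = 0.02
    error_rate: float = 0.001
    selection: dict | None = None  # {"chrom": ..., "locus1_bp", "locus2_bp", "s1", "s2"}
    seed: int = 0
    bh_q: float = 0.05
    het_threshold: float = 0.2
    truncation_fractions: tuple = (0.15, 0.25)  # per end: "-30%", "-50%"
    band_sigma: float = 2.33
    max_missing_frac: float = 0.1
    correct_distortion: bool = True
    selection_grid_step: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        chroms = [ChromosomeConfig(**c) for c in raw.pop("chromosomes", [])]
        cfg = cls(chromosomes=chroms, **raw)
        return cfg


#: study-like default geometry: Arabidopsis chromosome sizes and centromeres,
#: genetic lengths and interference strengths per sex
_DEFAULT_CHROMS = [
    # name, Mb, cen Mb, L_male (M), L_female (M), nu_m, nu_f, markers
    ("chr1", 30.43, 15.1, 1.59, 0.8129, 2.6, 2.7, 97),
    ("chr2", 19.70, 3.6, 0.945, 0.595, 2.5, 2.8, 63),
    ("chr3", 23.46, 13.8, 1.0678, 0.643, 2.5, 2.6, 75),
    ("chr4", 18.59, 4.0, 0.855, 0.55, 3.5, 4.1, 59),
    ("chr5", 26.98, 11.7, 1.2895, 0.719, 3.0, 3.5, 86),
]


def default_config(seed: int = 0, scale: float = 1.0) -> RunConfig:
    """The study-shaped configuration (~1,500 plants x 380 markers).

    ``scale`` < 1 shrinks plant and marker numbers proportionally for quick
    runs; chromosome geometry and model parameters are untouched.  The male
    chromosome-1 map carries two-locus gametic selection (retention 0.67 for
    the recurrent allele at 7,267,270 bp and 0.37 for the donor allele at
    26,188,466 bp), so its naive map length under-estimates the simulated
    1.59-Morgan truth.
    """
    chroms = [
        ChromosomeConfig(
            name=n,
            physical_mb=mb,
            centromere_mb=cen,
            genetic_length_male=lm,
            genetic_length_female=lf,
            nu_male=num,
            nu_female=nuf,
            n_markers=max(int(round(nm * scale)), 4),
        )
        for n, mb, cen, lm, lf, num, nuf, nm in _DEFAULT_CHROMS
    ]
    return RunConfig(
        chromosomes=chroms,
        n_plants_male=max(int(1505 * scale), 20),
        n_plants_female=max(int(1507 * scale), 20),
        selection={
            "chrom": "chr1",
            "locus1_bp": 7_267_270,
            "locus2_bp": 26_188_466,
            "s1": 0.67,
            "s2": 0.37,
        },
        seed=seed,
    )


def build_specs(config: RunConfig, sex: str) -> list[sim.ChromosomeSpec]:
    specs = []
    for c in config.chromosomes:
        phys = int(c.physical_mb * 1e6)
        markers = tuple(np.linspace(1, phys, c.n_markers).astype(int))
        cen = int(c.centromere_mb * 1e6)
        knots = c.map_knots_male if sex == "male" else c.map_knots_female
        specs.append(
            sim.ChromosomeSpec(
                name=c.name,
                genetic_length=(
                    c.genetic_length_male if sex == "male" else c.genetic_length_female
                ),
                physical_length=phys,
                marker_positions=markers,
                centromere_span=(max(cen - 1_000_000, 1), cen + 1_000_000),
                map_knots=tuple(map(tuple, knots)) if knots else None,
            )
        )
    return specs


def _simulate_sex(config: RunConfig, sex: str) -> "sim.GenotypeMatrix":
    specs = build_specs(config, sex)
    models = {
        c.name: sim.GammaModel(c.nu_male if sex == "male" else c.nu_female)
        for c in config.chromosomes
    }
    selection = None
    if config.selection and sex == "male":
        s = config.selection
        selection = {
            s["chrom"]: sim.SelectionModel(
                s["locus1_bp"], s["locus2_bp"], s["s1"], s["s2"],
                unfavored1=CODE_A, unfavored2=CODE_H,
            )
        }
    seed = np.random.SeedSequence([config.seed, 0 if sex == "male" else 1]).generate_state(1)[0]
    n = config.n_plants_male if sex == "male" else config.n_plants_female
    return sim.simulate_population(
        specs,
        models,
        n,
        int(seed),
        selection=selection,
        missing_rate=config.missing_rate,
        error_rate=config.error_rate,
        plant_prefix=f"{sex[0]}",
    )


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Run the full pipeline; returns the report dict (JSON-serializable)."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            "bh_q": config.bh_q,
            "het_threshold": config.het_threshold,
            "truncation_fractions": list(config.truncation_fractions),
            "band_sigma": config.band_sigma,
            "max_missing_frac": config.max_missing_frac,
        },
        "chromosomes": {},
    }
    matrices = {}
    for sex in ("male", "female"):
        log.info("simulating %s population", sex)
        m = _simulate_sex(config, sex)
        n_flags = len(flag_singletons(m))
        m = m.drop_high_missing_plants(config.max_missing_frac)
        matrices[sex] = m
        report[f"n_plants_{sex}"] = m.n_plants
        report[f"singleton_flags_{sex}"] = n_flags
        if out is not None:
            write_genotype_matrix(m, out / f"genotypes_{sex}.tsv")
            write_marker_map(m.marker_map, out / f"markers_{sex}.tsv")

    centromere_mid = {c.name: c.centromere_mb * 1e6 for c in config.chromosomes}
    lengths = {"male": {}, "female": {}}
    for c in config.chromosomes:
        entry: dict = {}
        for sex in ("male", "female"):
            m = matrices[sex]
            l_sum = mp.chromosome_length_interval_sum(m, c.name)
            l_switch = mp.chromosome_length_switch_count(m, c.name)
            lengths[sex][c.name] = l_switch
            s = itf.chromosome_co_summary(m, c.name)
            entry[sex] = {
                "cM_interval_sum": 100 * l_sum.morgans,
                "cM_switch_count": 100 * l_switch.morgans,
                "nu": s["nu"],
                "nu_ci": [s["nu_ci_lo"], s["nu_ci_hi"]],
                "poisson_p": s["poisson_p"],
            }
        ratio = mp.mf_ratio_ci(lengths["male"][c.name], lengths["female"][c.name])
        entry["mf_ratio"] = ratio.f
        entry["mf_ratio_ci"] = list(ratio.ci95)
        entry["mf_ttest_p"] = mp.compare_lengths_ttest(
            mp.per_plant_co_counts(matrices["male"], c.name),
            mp.per_plant_co_counts(matrices["female"], c.name),
        )
        for frac in config.truncation_fractions:
            lm = mp.chromosome_length_switch_count(
                mp.truncate_chromosome(matrices["male"], c.name, frac), c.name
            )
            lf = mp.chromosome_length_switch_count(
                mp.truncate_chromosome(matrices["female"], c.name, frac), c.name
            )
            entry[f"mf_ratio_trunc_{int(2 * frac * 100)}pct"] = (
                lm.morgans / lf.morgans if lf.morgans else None
            )
        report["chromosomes"][c.name] = entry

    # segregation distortion
    profile = dst.distortion_profile(matrices["male"], config.band_sigma)
    report["distortion"] = {
        "n_flagged_male": int(profile["flagged"].sum()),
        "n_markers": len(profile),
    }
    if config.selection and config.correct_distortion:
        s = config.selection
        m = matrices["male"]
        chrom = s["chrom"]
        pos = m.marker_map.positions(chrom)
        names = m.marker_map.markers(chrom)
        l1 = names[int(np.argmin(np.abs(pos - s["locus1_bp"])))]
        l2 = names[int(np.argmin(np.abs(pos - s["locus2_bp"])))]
        fit1 = dst.estimate_single_locus_fitness(m, l1)
        fit2 = dst.estimate_single_locus_fitness(m, l2)
        s1s, s2s, _ = dst.fit_selection_coefficients(
            m, l1, l2, grid_step=config.selection_grid_step
        )
        corr = dst.corrected_map_length(m, chrom, l1, l2, s1s, s2s)
        report["distortion"].update(
            {
                "loci": [l1, l2],
                "s_marginal": [fit1, fit2],
                "s_fitted": [s1s, s2s],
                "cM_naive": float(corr["cm_naive"].sum()),
                "cM_corrected": float(corr["cm_corrected"].sum()),
            }
        )
    elif not config.selection:
        report["distortion"]["correction"] = "skipped (no selection block)"

    # features on the male map (tracks are synthetic, seeded from the master seed)
    specs_m = build_specs(config, "male")
    hot_cold = {}
    associations = []
    for ci, (spec, c) in enumerate(zip(specs_m, config.chromosomes)):
        track_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7, ci])
        )
        feats, windows = sim.generate_feature_tracks(spec, track_rng)
        for sex in ("male", "female"):
            tab = mp.interval_table(matrices[sex], c.name)
            het = feat.infer_heterochromatin(windows, tab, config.het_threshold)
            classed = feat.classify_hot_cold(tab, centromere_mid, het)
            hot_cold.setdefault(sex, {"hot": 0, "cold": 0})
            hot_cold[sex]["hot"] += int(classed["hot"].sum())
            hot_cold[sex]["cold"] += int(classed["cold"].sum())
            for name in ("gc", "genes", "te", "cpg"):
                res = feat.associate_rate_feature(
                    tab["cm_per_mb"], feats[name], exclude=het
                )
                associations.append(
                    dict(chrom=c.name, sex=sex, feature=name, **res)
                )
    report["hot_cold"] = hot_cold
    report["associations"] = associations
    mf_sig = 0
    for c in config.chromosomes:
        cmp_tab = feat.compare_intervals_mf(
            mp.interval_table(matrices["male"], c.name),
            mp.interval_table(matrices["female"], c.name),
            q=config.bh_q,
        )
        mf_sig += int(cmp_tab["significant"].sum())
        if out is not None:
            write_interval_table(cmp_tab, out / f"mf_intervals_{c.name}.tsv")
    report["n_mf_significant_intervals"] = mf_sig

    # chromosome-size scaling (per-bivalent counts = 2 x Morgans)
    for sex in ("male", "female"):
        ls = [lengths[sex][c.name] for c in config.chromosomes]
        y = [l.morgans for l in ls]
        var = [l.variance for l in ls]
        mb = [c.physical_mb for c in config.chromosomes]
        lin = sc.fit_linear(mb, [2 * v for v in y])
        thr = sc.fit_threshold_model(y, mb, var)
        lif = sc.test_li_freudenberg(y, mb, var)
        report[f"scaling_{sex}"] = {
            "linear": lin,
            "threshold": {"slope": thr.slope, "L_thr_mb": thr.threshold,
                          "chi2": thr.chi2, "p": thr.p_value},
            "li_freudenberg": {"slope": lif.slope, "chi2": lif.chi2, "p": lif.p_value},
        }

    if out is not None:
        (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
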