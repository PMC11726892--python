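"""End-to-end orchestration: simulate -> qc -> call -> dml/dmr ->
annotate -> coenrich, driven by one flat key-value config.

One global seed deterministically derives per-stage seeds (CRC32 of
"stage-name/seed"), so identical config + seed reproduces every output
byte for byte and stages can be rerun independently.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import calling, coenrich, differential, simulate

log = logging.getLogger("rremtools")

DEFAULT_EFFECTS = ("DKO:p_h:0.02:0.2;WT-AOX:p_h:0.02:0.15;"
                   "DKO-AOX:p_h:0.02:0.25;DKO-AOX:p_m:0.01:0.15")

#: config defaults; thresholds mirror the analysis conventions
#: (delta 0.1, FDR 0.05, depth 10-100x, dynamic 20-80%, +/-50 bp
#: windows on a 100 bp binned track).
DEFAULTS: dict[str, object] = {
    "seed": 0,
    "n_chromosomes": 2,
    "chromosome_length": 1_000_000,
    "island_count": 20,
    "repeat_density": 0.10,
    "groups": "WT,DKO,WT-AOX,DKO-AOX",
    "replicates": 3,
    "effects": DEFAULT_EFFECTS,
    "mean_depth": 30.0,
    "spike_depth_multiplier": 10.0,
    "e_fail": 0.005,
    "e_over": 0.005,
    "e_seq": 0.001,
    "min_fragment": 40,
    "max_fragment": 400,
    "min_depth": 10,
    "max_depth": 100,
    "dynamic_lo": 0.2,
    "dynamic_hi": 0.8,
    "delta": 0.1,
    "fdr": 0.05,
    "dispersion_k": 10.0,
    "dmr_min_length": 50,
    "dmr_min_cpgs": 3,
    "dmr_merge_gap": 100,
    "dmr_min_sig_fraction": 0.5,
    "half_width": 50,
    "bin_width": 100,
    "tau": 0.1,
    "lesion_noise_sd": 0.25,
    "lesion_effect": 0.0,
    "lesion_n_enriched": 0,
    "log_level": "INFO",
}

#: condition contrasts evaluated when the groups are present
COMPARISONS = (("DKO", "WT"), ("WT-AOX", "WT"), ("DKO-AOX", "DKO"),
               ("DKO-AOX", "WT"))


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))
        self.errors = errors


def stage_seed(stage: str, global_seed: int) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}/{global_seed}".encode()) & 0x7FFFFFFF


def parse_effects(spec: str, groups: tuple[str, ...],
                  ) -> dict[str, list[simulate.EffectSpec]]:
    """Parse 'GROUP:target:fraction:delta;...' ('none' for no effects)."""
    out: dict[str, list[simulate.EffectSpec]] = {}
    if spec.strip().lower() in ("none", ""):
        return out
    for item in spec.split(";"):
        parts = item.strip().split(":")
        if len(parts) != 4:
            raise ValueError(f"bad effect spec {item!r} "
                             "(want GROUP:target:fraction:delta)")
        grp, target, fraction, delta = parts
        if grp not in groups:
            if spec == DEFAULT_EFFECTS:
                continue  # default effect table trimmed to a reduced design
            raise ValueError(f"effect group {grp!r} not among groups {groups}")
        eff = simulate.EffectSpec(float(fraction), target, float(delta))
        eff.validate()
        out.setdefault(grp, []).append(eff)
    return out


def validate_config(raw: dict | None) -> tuple[dict, list[str]]:
    """Fill defaults, coerce types, and collect all range errors."""
    raw = dict(raw or {})
    errors: list[str] = []
    cfg = dict(DEFAULTS)
    for key, value in raw.items():
        if key not in DEFAULTS:
            errors.append(f"unknown config key {key!r}")
            continue
        target_type = type(DEFAULTS[key])
        try:
            cfg[key] = target_type(value)
        except (TypeError, ValueError):
            errors.append(f"config key {key!r}: cannot coerce {value!r} "
                          f"to {target_type.__name__}")

    def check(cond: bool, msg: str) -> None:
        if not cond:
            errors.append(msg)

    check(0 <= float(cfg["delta"]) < 1, f"delta={cfg['delta']} outside [0, 1)")
    check(0 < float(cfg["fdr"]) < 1, f"fdr={cfg['fdr']} outside (0, 1)")
    check(int(cfg["min_depth"]) <= int(cfg["max_depth"]),
          "min_depth must be <= max_depth")
    check(0 <= float(cfg["dynamic_lo"]) <= float(cfg["dynamic_hi"]) <= 1,
          "dynamic window must satisfy 0 <= lo <= hi <= 1")
    check(int(cfg["bin_width"]) > 0, f"bin_width={cfg['bin_width']} must be > 0")
    check(int(cfg["half_width"]) > 0, f"half_width={cfg['half_width']} must be > 0")
    check(int(cfg["replicates"]) >= 1, "replicates must be >= 1")
    check(int(cfg["n_chromosomes"]) >= 1, "n_chromosomes must be >= 1")
    check(int(cfg["chromosome_length"]) >= 10_000,
          "chromosome_length must be >= 10000")
    check(0 <= int(cfg["min_fragment"]) <= int(cfg["max_fragment"]),
          "fragment size window invalid")
    for key in ("e_fail", "e_over", "e_seq"):
        check(0 <= float(cfg[key]) <= 0.5, f"{key}={cfg[key]} outside [0, 0.5]")
    check(float(cfg["tau"]) >= 0, "tau must be >= 0")
    check(float(cfg["lesion_noise_sd"]) >= 0, "lesion_noise_sd must be >= 0")
    check(float(cfg["dispersion_k"]) >= 0, "dispersion_k must be >= 0")
    check(0 <= float(cfg["dmr_min_sig_fraction"]) <= 1,
          "dmr_min_sig_fraction outside [0, 1]")

    groups = tuple(g.strip() for g in str(cfg["groups"]).split(",") if g.strip())
    check(len(groups) >= 1 and len(set(groups)) == len(groups),
          "groups must be non-empty and unique")
    try:
        parse_effects(str(cfg["effects"]), groups)
    except ValueError as exc:
        errors.append(str(exc))
    return cfg, errors


def load_config(path: str | Path | None) -> dict:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg, errors = validate_config(raw)
    if errors:
        raise ConfigError(errors)
    return cfg


def design_from_config(cfg: dict) -> simulate.StudyDesign:
    groups = tuple(g.strip() for g in str(cfg["groups"]).split(",") if g.strip())
    return simulate.StudyDesign(
        groups=groups,
        replicates=int(cfg["replicates"]),
        effects=parse_effects(str(cfg["effects"]), groups),
        mean_depth=float(cfg["mean_depth"]),
        spike_depth_multiplier=float(cfg["spike_depth_multiplier"]),
        e_fail=float(cfg["e_fail"]),
        e_over=float(cfg["e_over"]),
        e_seq=float(cfg["e_seq"]),
        seed=stage_seed("truth", int(cfg["seed"])),
    )


def sample_name(assay: str, group: str, rep: int) -> str:
    return f"{assay}_{group}_r{rep}"


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> dict:
    seed = int(cfg["seed"])
    sim_dir = outdir / "sim"
    calls_dir = sim_dir / "sitecalls"
    calls_dir.mkdir(parents=True, exist_ok=True)

    genome = simulate.generate_genome(
        stage_seed("genome", seed),
        n_chromosomes=int(cfg["n_chromosomes"]),
        chromosome_length=int(cfg["chromosome_length"]),
        island_count=int(cfg["island_count"]),
        repeat_density=float(cfg["repeat_density"]),
    )
    design = design_from_config(cfg)
    truths, ledger = simulate.generate_truth(genome, design)
    fragments = simulate.digest_genome(genome, int(cfg["min_fragment"]),
                                       int(cfg["max_fragment"]))

    simulate.write_fasta(genome, sim_dir / "genome.fa")
    simulate.write_annotation_beds(genome, sim_dir / "annotation")
    simulate.write_truth(truths, ledger, sim_dir / "truth")
    simulate.write_design(design, sim_dir / "design.cfg")

    sheet_rows = []
    n_calls = 0
    for group in design.groups:
        for rep in range(1, design.replicates + 1):
            for assay in simulate.ASSAYS:
                name = sample_name(assay, group, rep)
                rng = np.random.default_rng(
                    stage_seed(f"reads/{name}", seed))
                calls = simulate.simulate_reads(fragments, truths[group],
                                                assay, design, rng=rng)
                simulate.write_site_calls(calls, calls_dir / f"{name}.tsv")
                sheet_rows.append({"sample": name, "group": group,
                                   "assay": assay, "replicate": rep,
                                   "n_calls": len(calls)})
                n_calls += len(calls)
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(sim_dir / "sample_sheet.tsv", sep="\t", index=False)

    # lesion track: optionally spiked near true 5hmC effect sites so the
    # co-enrichment stage has a positive control to detect
    regions: list[tuple[str, int, int]] = []
    if float(cfg["lesion_effect"]) != 0 and int(cfg["lesion_n_enriched"]) > 0:
        hot = ledger[ledger["target"] == "p_h"]
        rng = np.random.default_rng(stage_seed("lesion-regions", seed))
        k = min(int(cfg["lesion_n_enriched"]), len(hot))
        pick = hot.iloc[rng.choice(len(hot), size=k, replace=False)] if k else hot
        half = int(cfg["half_width"])
        lengths = genome.contig_lengths()
        for row in pick.itertuples(index=False):
            s = max(0, int(row.pos) - half)
            e = min(lengths[row.contig], int(row.pos) + half)
            regions.append((row.contig, s, e))
    track = simulate.simulate_lesion_track(
        genome, bin_width=int(cfg["bin_width"]), enriched_regions=regions,
        effect=float(cfg["lesion_effect"]),
        noise_sd=float(cfg["lesion_noise_sd"]),
        seed=stage_seed("lesion", seed))
    coenrich.write_bedgraph(track, sim_dir / "lesion.bedGraph")

    return {"n_samples": len(sheet), "n_site_calls": n_calls,
            "n_cpg_sites": int(sum(len(t) for t in truths.values())
                               // max(len(truths), 1)),
            "n_effect_entries": len(ledger)}


def stage_qc(cfg: dict, outdir: Path) -> dict:
    sheet = pd.read_csv(outdir / "sim" / "sample_sheet.tsv", sep="\t")
    qc_dir = outdir / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in sheet.itertuples(index=False):
        counts = calling.aggregate_counts(
            outdir / "sim" / "sitecalls" / f"{row.sample}.tsv")
        rep = calling.spikein_qc(counts, row.assay,
                                 min_depth=int(cfg["min_depth"]))
        rows.append({
            "sample": row.sample, "assay": row.assay,
            "lambda_apparent": rep.lambda_apparent_modification,
            "lambda_ci_lo": rep.lambda_ci[0], "lambda_ci_hi": rep.lambda_ci[1],
            "puc19_apparent": rep.puc19_apparent_modification,
            "puc19_ci_lo": rep.puc19_ci[0], "puc19_ci_hi": rep.puc19_ci[1],
            "n_sites": rep.n_sites, "lambda_warning": rep.lambda_warning,
        })
    qc = pd.DataFrame(rows)
    qc.to_csv(qc_dir / "spikein_qc.tsv", sep="\t", index=False,
              float_format="%.6g")
    (qc_dir / "spikein_qc.json").write_text(
        json.dumps(qc.to_dict(orient="records"), indent=1))
    return {"n_samples": len(qc),
            "n_lambda_warnings": int(qc["lambda_warning"].sum())}


def stage_call(cfg: dict, outdir: Path) -> dict:
    sheet = pd.read_csv(outdir / "sim" / "sample_sheet.tsv", sep="\t")
    call_dir = outdir / "calls"
    call_dir.mkdir(parents=True, exist_ok=True)
    counts_in = counts_kept = dynamic_total = 0
    for row in sheet.itertuples(index=False):
        counts = calling.aggregate_counts(
            outdir / "sim" / "sitecalls" / f"{row.sample}.tsv")
        counts_in += len(counts)
        kept = calling.depth_filter(counts, int(cfg["min_depth"]),
                                    int(cfg["max_depth"]))
        counts_kept += len(kept)
        calling.write_coverage(kept, call_dir / f"{row.sample}.cov.tsv")
        levels = calling.with_levels(kept)
        dyn = calling.dynamic_subset(levels, float(cfg["dynamic_lo"]),
                                     float(cfg["dynamic_hi"]))
        dynamic_total += len(dyn)
    return {"sites_in": counts_in, "sites_depth_filtered": counts_kept,
            "dynamic_site_records": dynamic_total}


def _replicate_counts(outdir: Path, sheet: pd.DataFrame, assay: str,
                      group: str, main_only: bool = True) -> list[pd.DataFrame]:
    out = []
    sel = sheet[(sheet["assay"] == assay) & (sheet["group"] == group)]
    for row in sel.itertuples(index=False):
        c = calling.read_coverage(outdir / "calls" / f"{row.sample}.cov.tsv")
        if main_only:
            c = c[~c["contig"].isin(simulate.SPIKE_CONTIGS)].reset_index(drop=True)
        out.append(c)
    return out


def stage_differential(cfg: dict, outdir: Path) -> dict:
    sheet = pd.read_csv(outdir / "sim" / "sample_sheet.tsv", sep="\t")
    groups = sheet["group"].unique().tolist()
    dml_dir = outdir / "dml"
    dml_dir.mkdir(parents=True, exist_ok=True)
    tconf = differential.TestConfig(
        delta=float(cfg["delta"]), fdr_threshold=float(cfg["fdr"]),
        dispersion_k=float(cfg["dispersion_k"]),
        dmr_min_length=int(cfg["dmr_min_length"]),
        dmr_min_cpgs=int(cfg["dmr_min_cpgs"]),
        dmr_merge_gap=int(cfg["dmr_merge_gap"]),
        dmr_min_sig_fraction=float(cfg["dmr_min_sig_fraction"]))

    summary: dict[str, dict] = {}
    for g1, g2 in COMPARISONS:
        if g1 not in groups or g2 not in groups:
            continue
        for assay in simulate.ASSAYS:
            tag = f"{assay}_{g1}_vs_{g2}"
            c1 = _replicate_counts(outdir, sheet, assay, g1)
            c2 = _replicate_counts(outdir, sheet, assay, g2)
            dml, counts = differential.dml_test(c1, c2, tconf)
            dmr = differential.call_dmr(dml, tconf)
            dml.to_csv(dml_dir / f"dml_{tag}.tsv", sep="\t", index=False,
                       float_format="%.6g")
            dmr.to_csv(dml_dir / f"dmr_{tag}.tsv", sep="\t", index=False,
                       float_format="%.6g")
            with open(dml_dir / f"dmr_{tag}.bed", "w") as fh:
                for r in dmr.itertuples(index=False):
                    fh.write(f"{r.contig}\t{r.start}\t{r.end}\t"
                             f"{r.direction}\t{r.n_cpgs}\n")
            summary[tag] = {"tested": len(dml), **counts, "dmr": len(dmr)}
    return summary


def stage_annotate(cfg: dict, outdir: Path) -> dict:
    sheet = pd.read_csv(outdir / "sim" / "sample_sheet.tsv", sep="\t")
    ann_dir = outdir / "annotate"
    ann_dir.mkdir(parents=True, exist_ok=True)

    raw: dict[str, list[tuple[str, int, int]]] = {}
    for bed in sorted((outdir / "sim" / "annotation").glob("*.bed")):
        cat = bed.stem
        ivals = []
        with open(bed) as fh:
            for line in fh:
                contig, s, e, *_ = line.split("\t")
                ivals.append((contig, int(s), int(e)))
        raw[cat] = ivals
    lengths = {}
    for contig, sub in pd.concat(
            [pd.DataFrame(v, columns=["contig", "s", "e"]) for v in raw.values()],
            ignore_index=True).groupby("contig"):
        lengths[contig] = int(sub["e"].max())
    flat = ann_mod.flatten_annotation(raw, lengths)

    groups = sheet["group"].unique().tolist()
    enrich_by = {}
    n_rows = 0
    for assay in simulate.ASSAYS:
        for group in groups:
            reps = _replicate_counts(outdir, sheet, assay, group)
            per_rep = []
            merged_dyn = []
            for c in reps:
                levels = calling.with_levels(c)
                dyn = calling.dynamic_subset(levels, float(cfg["dynamic_lo"]),
                                             float(cfg["dynamic_hi"]))
                if dyn.empty or levels.empty:
                    continue
                bg_cats = ann_mod.annotate_sites(levels, flat)
                dyn_cats = ann_mod.annotate_sites(dyn, flat)
                per_rep.append(ann_mod.log2_obs_exp(dyn_cats, bg_cats))
                merged_dyn.append(dyn)
            if not per_rep:
                continue
            enrich_by[(assay, group)] = per_rep
            merged = pd.concat(merged_dyn, ignore_index=True)
            dist = ann_mod.distribution(ann_mod.annotate_sites(merged, flat))
            dist.rename("percent").to_csv(
                ann_dir / f"distribution_{assay}_{group}.tsv", sep="\t",
                header=True, index_label="category", float_format="%.6g")
            combined = pd.concat(
                [df.assign(replicate=i + 1) for i, df in enumerate(per_rep)],
                ignore_index=True)
            combined.to_csv(ann_dir / f"enrichment_{assay}_{group}.tsv",
                            sep="\t", index=False, float_format="%.6g")
            n_rows += len(combined)

    n_comparisons = 0
    for g1, g2 in COMPARISONS:
        for assay in simulate.ASSAYS:
            if (assay, g1) in enrich_by and (assay, g2) in enrich_by:
                comp = ann_mod.compare_replicate_enrichment(
                    enrich_by[(assay, g1)], enrich_by[(assay, g2)])
                comp.to_csv(ann_dir / f"enrichment_mw_{assay}_{g1}_vs_{g2}.tsv",
                            sep="\t", index=False, float_format="%.6g")
                n_comparisons += 1
    return {"enrichment_rows": n_rows, "comparisons": n_comparisons}


def stage_coenrich(cfg: dict, outdir: Path) -> dict:
    seed = int(cfg["seed"])
    sheet = pd.read_csv(outdir / "sim" / "sample_sheet.tsv", sep="\t")
    co_dir = outdir / "coenrich"
    co_dir.mkdir(parents=True, exist_ok=True)
    track = coenrich.read_bedgraph(outdir / "sim" / "lesion.bedGraph")

    per_chrom = coenrich.per_chromosome_summary(track)
    per_chrom.to_csv(co_dir / "per_chromosome.tsv", sep="\t", index=False,
                     float_format="%.6g")

    # 5hmC DML between the first available contrast with any DML
    groups = sheet["group"].unique().tolist()
    result: dict[str, object] = {"per_chromosome_contigs": len(per_chrom)}
    for g1, g2 in COMPARISONS:
        if g1 not in groups or g2 not in groups:
            continue
        path = outdir / "dml" / f"dml_RREhM_{g1}_vs_{g2}.tsv"
        if not path.exists():
            continue
        dml = pd.read_csv(path, sep="\t")
        hits = dml[dml["is_dml"]]
        if hits.empty:
            result[f"{g1}_vs_{g2}"] = "no DML; co-enrichment skipped"
            continue
        pool = dml[["contig", "pos"]]
        rng = np.random.default_rng(stage_seed(f"coenrich/{g1}/{g2}", seed))
        try:
            rand = coenrich.sample_random_loci(pool, hits, len(hits), rng)
        except ValueError as exc:
            result[f"{g1}_vs_{g2}"] = f"skipped: {exc}"
            continue
        half = int(cfg["half_width"])
        d_scores = coenrich.window_scores(track, hits, half)
        r_scores = coenrich.window_scores(track, rand, half)
        comp = coenrich.compare_sets(d_scores["score"], r_scores["score"],
                                     tau=float(cfg["tau"]))
        d_scores.assign(set="dml").to_csv(
            co_dir / f"scores_dml_{g1}_vs_{g2}.tsv", sep="\t", index=False,
            float_format="%.6g")
        r_scores.assign(set="random").to_csv(
            co_dir / f"scores_random_{g1}_vs_{g2}.tsv", sep="\t", index=False,
            float_format="%.6g")
        result[f"{g1}_vs_{g2}"] = {
            "n": comp.n, "dml_median": comp.dml_median,
            "random_median": comp.random_median, "mw_p": comp.mw_p,
            "verdict": comp.verdict,
        }
    pd.DataFrame([{"comparison": k, "result": json.dumps(v)}
                  for k, v in result.items()]).to_csv(
        co_dir / "comparison_summary.tsv", sep="\t", index=False)
    return result


STAGES = (
    ("simulate", stage_simulate),
    ("qc", stage_qc),
    ("call", stage_call),
    ("differential", stage_differential),
    ("annotate", stage_annotate),
    ("coenrich", stage_coenrich),
)


def run_all(cfg: dict, outdir: str | Path) -> dict:
    """Run every stage; returns (and writes) the machine-readable report."""
    cfg, errors = validate_config(cfg)
    if errors:
        raise ConfigError(errors)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]), logging.INFO))

    report: dict = {"config": {k: cfg[k] for k in sorted(cfg)}, "stages": {}}
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            out = fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        log.info("stage %s finished in %.1fs", name, dt)
        report["stages"][name] = {"seconds": round(dt, 3), "summary": out}
    (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                   default=str))
    return report
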