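"""End-to-end pipeline stages: merge, consensus, Hi-C detection, demo.

Each stage is a plain function over library objects; the click commands in
:mod:`multisv.cli` are thin wrappers.  All stages log per-stage record counts
so the conservation invariants are auditable from the logs, and all outputs
are free of timestamps so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import consensus as cons
from . import evaluate as ev
from . import hic
from . import merge as mg
from . import orthomatch as om
from . import simulate as sim
from .config import PipelineConfig
from .core import CallSet, GenomicRegionSet, Provenance, SVRecord
from .vcfio import read_bed_regions, read_sv_vcf, write_bed_regions, write_sv_vcf

log = logging.getLogger("multisv")


def read_manifest(path) -> list[CallSet]:
    """Load the call sets listed in a manifest TSV.

    Columns: path, platform, tool, replicate, sample.  Paths are relative to
    the manifest's directory.
    """
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"path", "platform", "tool", "replicate", "sample"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    callsets = []
    for _, row in df.iterrows():
        vcf = base / row["path"]
        if not vcf.exists():
            raise FileNotFoundError(str(vcf))
        prov = Provenance(row["platform"], row["tool"], row["replicate"], row["sample"])
        callsets.append(read_sv_vcf(vcf, prov))
    return callsets


def _bucket_all(callsets, cfg):
    """Split every call set; returns {(class, is_tra): {prov: CallSet}}."""
    buckets: dict = {}
    for cs in callsets:
        for key, sub in mg.split_by_size_and_type(cs, cfg).items():
            buckets.setdefault(key, []).append(sub)
    return buckets


def _members_to_callsets(merged: list[mg.MergedSV]) -> list[CallSet]:
    by_prov: dict = {}
    for sv in merged:
        for rec, prov in sv.members:
            by_prov.setdefault(prov, []).append(rec)
    return [
        CallSet(provenance=p, records=recs).sort()
        for p, recs in sorted(by_prov.items(), key=lambda kv: kv[0].callset_key)
    ]


def run_merge(callsets: list[CallSet], config: PipelineConfig) -> list[mg.MergedSV]:
    """split -> per-callset somatic subtraction -> cross-tool merge -> cluster.

    For every (platform, tool, replicate) the tumor call set is reduced to
    calls absent from its matched normal at the size class's window; somatic
    calls from all call sets are then merged per size class and finally
    clustered by type and >50% reciprocal size similarity.
    """
    cfg = config.size_class_config()
    tumor = [cs for cs in callsets if cs.provenance.sample == "tumor"]
    normal = {
        cs.provenance.callset_key: cs
        for cs in callsets
        if cs.provenance.sample == "normal"
    }
    log.info("merge: %d tumor / %d normal call sets", len(tumor), len(normal))

    somatic_by_bucket: dict = {}
    n_somatic = 0
    for cs in tumor:
        mate = normal.get(cs.provenance.callset_key)
        t_buckets = mg.split_by_size_and_type(cs, cfg)
        n_buckets = mg.split_by_size_and_type(mate, cfg) if mate else {}
        for key, t_sub in t_buckets.items():
            window = cfg.large_window if key[1] else cfg.window_of_class(key[0])
            t_merged = mg.merge_calls([t_sub], window, cfg=cfg)
            n_sub = n_buckets.get(key)
            if n_sub is not None:
                n_merged = mg.merge_calls([n_sub], window, cfg=cfg)
                t_merged = mg.somatic_subtract(t_merged, n_merged, window)
            somatic_by_bucket.setdefault(key, []).extend(t_merged)
            n_somatic += sum(len(m.members) for m in t_merged)
    log.info("merge: %d somatic member records after tumor-normal subtraction",
             n_somatic)

    merged_all: list[mg.MergedSV] = []
    for key in sorted(somatic_by_bucket):
        window = cfg.large_window if key[1] else cfg.window_of_class(key[0])
        stage = mg.merge_calls(
            _members_to_callsets(somatic_by_bucket[key]), window, cfg=cfg
        )
        log.info("merge: bucket %s -> %d clusters", key, len(stage))
        merged_all.extend(stage)

    clustered = mg.cluster_merged(merged_all, cfg)
    log.info("merge: %d clusters after reciprocal-size clustering", len(clustered))
    return clustered


def run_consensus(
    merged: list[mg.MergedSV],
    census: cons.ReplicateCensus,
    config: PipelineConfig,
    blacklist: GenomicRegionSet | None = None,
    loh: GenomicRegionSet | None = None,
):
    """Score clusters and select the initial and high-confidence call sets."""
    if config.exclude_tenx_del_below_bp:
        merged = cons.exclude_platform_calls(
            merged, cons.tenx_small_deletion_filter(config.exclude_tenx_del_below_bp)
        )
    records = cons.score_records(merged, census)
    initial = cons.select_initial(records, blacklist, config.min_replicates)
    high = cons.select_high_confidence(
        initial, loh, config.min_platforms, config.min_tools
    )
    log.info("consensus: %d scored / %d initial / %d high-confidence",
             len(records), len(initial), len(high))
    return records, initial, high


def summarize_by_type(records) -> dict:
    counts: dict = {}
    for r in records:
        counts[r.merged.svtype] = counts.get(r.merged.svtype, 0) + 1
    return dict(sorted(counts.items()))


def run_hic(matrix: hic.ContactMatrix, config: PipelineConfig,
            refine_matrix: hic.ContactMatrix | None = None):
    """Detect, filter, refine and classify junctions in a contact matrix."""
    cands = hic.detect_junctions(
        matrix,
        R=config.hic_quadrant_range_bins,
        Z_min=config.hic_z_min,
        local_max_range_bins=config.hic_local_max_range_bins,
        min_score=config.hic_min_score,
        min_quadrant_mass=config.hic_min_quadrant_mass,
        refine_matrix=refine_matrix,
        half_window_bp=config.hic_refine_half_window_bp,
        decay_bp=config.hic_refine_decay_bp,
        theta=config.hic_theta,
    )
    log.info("hic: %d junction candidates after filtering", len(cands))
    return cands


def _consensus_callset(records, name="consensus") -> CallSet:
    reps = []
    for i, r in enumerate(records):
        rep = r.merged.representative
        reps.append(
            SVRecord(f"{name}_{i:05d}", rep.svtype, rep.bnd1, rep.bnd2,
                     size=rep.size if rep.svtype == "INS" else -1,
                     info=dict(rep.info))
        )
    return CallSet(
        provenance=Provenance("Illumina", name, "1", "tumor"), records=reps
    ).sort()


def write_study(outdir, truth: sim.TruthSet, callsets, genome: sim.GenomeModel,
                loh_regions=None) -> Path:
    """Write a synthetic study to disk: VCF per call set, truth VCF,
    blacklist/LOH BEDs, and a manifest TSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cs in callsets:
        p = cs.provenance
        fname = f"{p.platform}_{p.tool}_r{p.replicate}_{p.sample}.vcf"
        write_sv_vcf(cs, outdir / fname)
        rows.append(
            {"path": fname, "platform": p.platform, "tool": p.tool,
             "replicate": p.replicate, "sample": p.sample}
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    truth_cs = CallSet(
        provenance=Provenance("Illumina", "truth", "1", "tumor"),
        records=truth.somatic + truth.germline,
    ).sort()
    write_sv_vcf(truth_cs, outdir / "truth.vcf")
    write_bed_regions(GenomicRegionSet(genome.blacklist, "blacklist"),
                      outdir / "blacklist.bed")
    if loh_regions:
        write_bed_regions(GenomicRegionSet(loh_regions, "LOH"), outdir / "loh.bed")
    return manifest


def default_loh_regions(genome: sim.GenomeModel) -> list:
    """Synthetic analogue of the normal-LOH exclusion regions: the terminal
    megabase of the last chromosome."""
    last = list(genome.chromosomes)[-1]
    length = genome.chromosomes[last]
    return [(last, max(0, length - 1_000_000), length)]


def run_demo(outdir, seed: int = 0, config: PipelineConfig | None = None) -> dict:
    """Simulate -> merge -> consensus -> Hi-C -> match -> evaluate.

    Returns the summary dict that is also written to ``summary.json``.
    """
    config = (config or PipelineConfig()).validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = sim.GenomeModel.toy(seed=seed)
    truth = sim.simulate_truth(genome, seed=seed + 1)
    callsets = sim.emulate_callsets(truth, genome, seed=seed + 2)
    loh = default_loh_regions(genome)
    manifest = write_study(outdir / "data", truth, callsets, genome, loh)

    callsets = read_manifest(manifest)
    merged = run_merge(callsets, config)
    census = cons.ReplicateCensus.from_callsets(
        [cs for cs in callsets if cs.provenance.sample == "tumor"]
    )
    blacklist = read_bed_regions(outdir / "data" / "blacklist.bed", "blacklist")
    loh_set = read_bed_regions(outdir / "data" / "loh.bed", "LOH")
    records, initial, high = run_consensus(merged, census, config, blacklist, loh_set)

    cons.consensus_to_dataframe(records).to_csv(
        outdir / "consensus.tsv", sep="\t", index=False
    )
    write_sv_vcf(_consensus_callset(initial, "initial"), outdir / "initial.vcf")
    write_sv_vcf(_consensus_callset(high, "highconf"), outdir / "high_confidence.vcf")

    # Hi-C: large-event detection on a simulated contact map
    hic_truth = [
        r for r in truth.somatic
        if r.svtype == "TRA" or (r.svtype in ("DEL", "DUP", "INV") and r.size >= 2_000_000)
    ]
    matrix = sim.simulate_hic(
        genome, w=config.hic_bin_width_bp, depth=5.0, truth_svs=truth.somatic,
        signal_factor=5.0, seed=seed + 3,
    )
    matrix.to_triplets(outdir / "hic_contacts.tsv")
    cands = run_hic(matrix, config)
    hic.candidates_to_dataframe(cands).to_csv(
        outdir / "hic_candidates.tsv", sep="\t", index=False
    )
    hic.candidates_to_bedpe(cands, outdir / "hic_junctions.bedpe", matrix.w)

    # orthogonal validation against a synthetic optical-mapping platform
    bn_sets = sim.emulate_callsets(
        truth, genome, profiles=[sim.bionano_profile()], seed=seed + 4
    )
    bn_tumor = [cs for cs in bn_sets if cs.provenance.sample == "tumor"]
    bn_normal = [r for cs in bn_sets if cs.provenance.sample == "normal"
                 for r in cs.records]
    bn_consensus = om.replicate_consensus(bn_tumor, 2, normal=bn_normal)
    high_reps = [r.merged.representative for r in high]
    match = om.match_calls(high_reps, bn_consensus)
    match.to_dataframe().to_csv(outdir / "validation.tsv", sep="\t", index=False)

    # evaluation: truth recall, platform sensitivity, purity titration
    eval_initial = ev.recall_precision([r.merged for r in initial], truth)
    eval_high = ev.recall_precision([r.merged for r in high], truth)
    by_platform = {}
    for cs in callsets:
        if cs.provenance.sample == "tumor":
            by_platform.setdefault(cs.provenance.platform, []).extend(cs.records)
    sens = ev.relative_sensitivity(by_platform)
    sens.table.to_csv(outdir / "relative_sensitivity.tsv", sep="\t")
    series = sim.simulate_purity_series(truth, seed=seed + 5)
    curves = ev.purity_depth_curves(series, truth)
    curves.to_csv(outdir / "purity_curves.tsv", sep="\t", index=False)
    ev.plot_recall_curves(curves, outdir / "purity_curves.png")

    summary = {
        "seed": seed,
        "n_truth_somatic": len(truth.somatic),
        "n_callsets": len(callsets),
        "n_merged_clusters": len(merged),
        "n_initial": len(initial),
        "n_high_confidence": len(high),
        "initial_by_type": summarize_by_type(initial),
        "high_confidence_by_type": summarize_by_type(high),
        "initial_recall": eval_initial.recall,
        "initial_precision": eval_initial.precision,
        "high_confidence_recall": eval_high.recall,
        "high_confidence_precision": eval_high.precision,
        "n_hic_candidates": len(cands),
        "n_hic_truth_junctions": len(hic_truth),
        "n_validation_matched": match.n_matched,
        "n_validation_queries": len(high_reps),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
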