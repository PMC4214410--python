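"""End-to-end pipeline: simulate -> merge -> scaffold -> profile -> selection -> mite.

Each stage reads the previous stage's in-memory products, writes its
outputs under ``<outdir>/<stage>/`` in standard formats, and is recorded in
a run manifest (config echo, per-stage output checksums, wall time).  One
global seed fans out to fixed per-stage streams, so a rerun with the same
config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dna, formats
from .merge import Contig, compute_overlaps, filter_redundant_contigs, olc_merge
from .mite import (
    associate,
    association_permutation_pvalue,
    compare_presence,
    detect_in_regions,
    diff_expression,
    extract_upstream,
)
from .profile import (
    call_het_variants,
    compare_assemblies,
    estimate_genome_size,
    kmer_spectrum,
    variant_venn,
)
from .scaffold import (
    assembly_stats,
    emit_pseudomolecule,
    hierarchical_scaffold,
    mega_scaffold,
    scaffold_sequence,
)
from .selection import find_orthologues, selection_scan
from .sim import (
    SimulationConfig,
    diverge_lineages,
    generate_ancestral_genome,
    make_diploid,
    plant_mites,
    shred_gapped,
    shred_overlapping,
    simulate_bac_and_fpc,
    simulate_expression,
    stage_rng,
)
from .sim.mites import make_element
from .sim.reads import simulate_tiers

ALL_STAGES = ("simulate", "merge", "scaffold", "profile", "selection", "mite")

#: RunConfig keys accepted outside the simulation block
_TOP_KEYS = {
    "seed",
    "stages",
    "simulation",
    "min_support",
    "min_identity",
    "min_containment",
    "min_overlap",
    "max_error",
    "neutral_tolerance",
    "alpha",
    "window",
    "kmer_k",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_support: int = 3
    min_identity: float = 0.95
    min_containment: float = 0.90
    min_overlap: int = 50
    max_error: float = 0.02
    neutral_tolerance: float = 0.1
    alpha: float = 0.05
    window: int = 1000
    kmer_k: int = 17

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        sim = d.pop("simulation", {})
        if not isinstance(sim, SimulationConfig):
            known = set(SimulationConfig.__dataclass_fields__)
            bad = set(sim) - known
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            if "insert_tiers" in sim:
                sim["insert_tiers"] = tuple(tuple(t) for t in sim["insert_tiers"])
            if "selection_profile" in sim:
                sim["selection_profile"] = tuple(tuple(t) for t in sim["selection_profile"])
            sim = SimulationConfig(**sim)
        stages = tuple(d.pop("stages", ALL_STAGES))
        for s in stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        cfg = cls(simulation=sim, stages=stages, **d)
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _TOP_KEYS if k not in ("simulation", "stages", "log_level")}
        d["stages"] = list(self.stages)
        d["simulation"] = self.simulation.to_dict()
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _checksum_dir(stage_dir: Path) -> dict[str, str]:
    return {
        p.name: formats.sha256_file(p)
        for p in sorted(stage_dir.iterdir())
        if p.is_file()
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``).  A missing
    upstream product raises :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    seed = config.seed
    manifest: dict = {
        "tool": "manihot",
        "config": config.to_dict(),
        "stages": {},
    }
    state: dict = {}

    def record(stage: str, t0: float) -> None:
        sd = outdir / stage
        manifest["stages"][stage] = {
            "outputs": _checksum_dir(sd),
            "seconds": round(time.time() - t0, 3),
        }

    if "simulate" in config.stages:
        t0 = time.time()
        sd = outdir / "simulate"
        sd.mkdir(exist_ok=True)
        ancestor, genes = generate_ancestral_genome(sim, stage_rng(seed, "genome"))
        lineages = diverge_lineages(ancestor, genes, sim, stage_rng(seed, "divergence"))
        mrng = stage_rng(seed, "mites")
        # MITE plan: shared elements are planted into both genomes,
        # lineage-specific ones into a single genome
        shared_ids = set(lineages.gene_truth.gene_id)
        plan_wild: dict[str, np.ndarray] = {}
        plan_cult: dict[str, np.ndarray] = {}
        mite_class: dict[str, str] = {}
        for gid in sorted(g.id for g in lineages.ancestor_genes):
            u = mrng.random()
            if u < sim.mite_shared_prob:
                entry = (make_element(mrng)[0], mrng.random())
                plan_wild[gid] = entry
                plan_cult[gid] = entry
                mite_class[gid] = "shared"
            elif u < sim.mite_shared_prob + sim.mite_insertion_prob / 2:
                plan_wild[gid] = (make_element(mrng)[0], mrng.random())
                mite_class[gid] = "wild"
            elif u < sim.mite_shared_prob + sim.mite_insertion_prob:
                plan_cult[gid] = (make_element(mrng)[0], mrng.random())
                mite_class[gid] = "cultivar"
        wild, wild_genes, wild_mites = plant_mites(
            lineages.wild, lineages.wild_genes, mrng, window=sim.upstream_window, plan=plan_wild
        )
        cult, cult_genes, cult_mites = plant_mites(
            lineages.cultivar, lineages.cultivar_genes, mrng, window=sim.upstream_window, plan=plan_cult
        )
        hap2, het_truth = make_diploid(
            wild, sim.het_snv_rate, sim.het_indel_rate, stage_rng(seed, "diploid")
        )
        tiers = simulate_tiers(
            (wild, hap2), sim.insert_tiers, sim.read_length, sim.error_rate, stage_rng(seed, "reads")
        )
        bac, fpc = simulate_bac_and_fpc(
            wild, sim.bac_clone_count, sim.bac_insert_mean, sim.bac_insert_sd,
            sim.bac_end_read_length, stage_rng(seed, "bac"),
        )
        suppressed = [
            mite_class.get(g.id) == "cultivar" for g in lineages.ancestor_genes
        ]
        counts, expr_truth = simulate_expression(
            [g.id for g in lineages.ancestor_genes],
            suppressed,
            sim.suppression_log2fc,
            sim.nb_dispersion,
            sim.n_replicates,
            stage_rng(seed, "expression"),
            base_mean=sim.expression_mean,
        )
        formats.write_fasta(sd / "ancestor.fasta", [("ancestor", ancestor)])
        formats.write_fasta(sd / "wild.fasta", [("wild", wild)])
        formats.write_fasta(sd / "wild_hap2.fasta", [("wild_hap2", hap2)])
        formats.write_fasta(sd / "cultivar.fasta", [("cultivar", cult)])
        formats.write_gff3(sd / "wild_genes.gff3", wild_genes, seqid="wild")
        formats.write_gff3(sd / "cultivar_genes.gff3", cult_genes, seqid="cultivar")
        formats.write_vcf(sd / "divergence_truth.vcf", lineages.variant_truth, ancestor, chrom="ancestor")
        formats.write_vcf(sd / "het_truth.vcf", het_truth, wild, chrom="wild")
        formats.write_tsv(sd / "gene_truth.tsv", lineages.gene_truth)
        formats.write_tsv(sd / "mite_truth_wild.tsv", wild_mites)
        formats.write_tsv(sd / "mite_truth_cultivar.tsv", cult_mites)
        formats.write_tsv(sd / "fpc_map.tsv", fpc.to_frame())
        formats.write_tsv(sd / "expression_counts.tsv", counts, index=True)
        formats.write_tsv(sd / "expression_truth.tsv", expr_truth, index=True)
        for rp in tiers:
            formats.write_fastq_pair(sd / f"reads_{rp.tier}", rp)
        state.update(
            ancestor=ancestor, genes=genes, lineages=lineages,
            wild=wild, wild_genes=wild_genes, wild_mites=wild_mites,
            cult=cult, cult_genes=cult_genes, cult_mites=cult_mites,
            hap2=hap2, het_truth=het_truth, tiers=tiers, bac=bac, fpc=fpc,
            counts=counts, mite_class=mite_class,
        )
        record("simulate", t0)

    if "merge" in config.stages:
        t0 = time.time()
        if "wild" not in state:
            raise StageError("merge", "missing upstream simulate outputs")
        sd = outdir / "merge"
        sd.mkdir(exist_ok=True)
        wild = state["wild"]
        # two offset fragmentations emulating long-read and short-read
        # assemblies: the half-phase second set bridges every junction of
        # the first, and a few mutated duplicates exercise the filter
        frags_a, _ = shred_overlapping(wild, 9000, 0)
        frags_b, _ = shred_overlapping(wild[4500:], 9000, 0)
        set_a = [Contig(f"a_{cid}", seq, source="setA") for cid, seq in frags_a]
        set_b = [Contig(f"b_{cid}", seq, source="setB") for cid, seq in frags_b]
        dup_rng = stage_rng(seed, "other")
        for c in set_a[:3]:
            seq = c.seq.copy()
            mut = dup_rng.choice(len(seq), max(1, len(seq) // 100), replace=False)
            seq[mut] = (seq[mut] + 1) % 4
            set_b.append(Contig(f"dup_{c.id}", seq, source="setB"))
        kept, decisions = filter_redundant_contigs(
            set_a, set_b, config.min_identity, config.min_containment
        )
        pool = set_a + kept
        overlaps = compute_overlaps(pool, config.min_overlap, config.max_error)
        merged, mlog = olc_merge(pool, overlaps)
        formats.write_fasta(sd / "merged.fasta", [(c.id, c.seq) for c in merged])
        formats.write_tsv(
            sd / "overlaps.tsv",
            pd.DataFrame(
                [(o.a_id, o.b_id, o.orientation, o.length, round(o.identity, 5)) for o in overlaps],
                columns=["a_id", "b_id", "orientation", "length", "identity"],
            ),
        )
        (sd / "merge.log").write_text("\n".join(
            [f"filter {d.contig_id}: removed={d.removed} best={d.best_primary}" for d in decisions]
            + mlog
        ) + "\n")
        state["merged"] = merged
        record("merge", t0)

    if "scaffold" in config.stages:
        t0 = time.time()
        if "wild" not in state:
            raise StageError("scaffold", "missing upstream simulate outputs")
        sd = outdir / "scaffold"
        sd.mkdir(exist_ok=True)
        wild = state["wild"]
        srng = stage_rng(seed, "other")
        contigs, layout = shred_gapped(
            wild, 20_000, 5_000, 150, 50, srng, big_gap_prob=0.06,
            big_gap_mean=int(1.3 * max(t[0] for t in sim.insert_tiers)),
        )
        scaffolds, slog = hierarchical_scaffold(
            contigs, state["tiers"], min_support=config.min_support
        )
        cd = dict(contigs)
        megas, mlog = mega_scaffold(scaffolds, cd, state["bac"], state["fpc"])
        seqs = []
        agps = []
        for m in megas:
            seq, agp = emit_pseudomolecule(m, cd)
            seqs.append((m.id, seq))
            agps.append(agp)
        formats.write_fasta(sd / "pseudomolecules.fasta", seqs)
        formats.write_agp(sd / "pseudomolecules.agp", pd.concat(agps, ignore_index=True))
        formats.write_tsv(sd / "contig_layout_truth.tsv", layout)
        st = assembly_stats([s for _, s in seqs])
        (sd / "stats.json").write_text(json.dumps({
            "total_bp": st.total_bp, "contig_count": st.contig_count,
            "n50": st.n50, "non_gapped_fraction": round(st.non_gapped_fraction, 6),
        }, indent=2) + "\n")
        (sd / "scaffold.log").write_text("\n".join(slog + mlog) + "\n")
        state["megas"] = megas
        record("scaffold", t0)

    if "profile" in config.stages:
        t0 = time.time()
        if "tiers" not in state:
            raise StageError("profile", "missing upstream simulate outputs")
        sd = outdir / "profile"
        sd.mkdir(exist_ok=True)
        wild, cult, ancestor = state["wild"], state["cult"], state["ancestor"]
        pe = state["tiers"][0]
        spec = kmer_spectrum([pe], k=config.kmer_k)
        est = estimate_genome_size(spec)
        formats.write_tsv(
            sd / "kmer_spectrum.tsv",
            pd.DataFrame({"depth": np.arange(len(spec.histogram)), "count": spec.histogram}),
        )
        calls, het_summary = call_het_variants(wild, state["tiers"][:1])
        formats.write_vcf(sd / "het_calls.vcf", calls, wild, chrom="wild")
        cmp_calls, div_summary = compare_assemblies(wild, cult)
        wa_calls, _ = compare_assemblies(wild, ancestor)
        ca_calls, _ = compare_assemblies(cult, ancestor)
        venn = variant_venn({"wild": wa_calls, "cultivar": ca_calls})
        (sd / "profile.json").write_text(json.dumps({
            "genome_size_estimate_bp": round(est.size_bp),
            "kmer_peak_depth": est.peak_depth,
            "het_snv_per_kb": round(het_summary.snv_per_kb, 4),
            "het_indel_per_kb": round(het_summary.indel_per_kb, 4),
            "divergence_snv_per_kb": round(div_summary.snv_per_kb, 4),
            "divergence_indel_per_kb": round(div_summary.indel_per_kb, 4),
            "venn": {"|".join(sorted(k)): v for k, v in venn.items()},
        }, indent=2) + "\n")
        record("profile", t0)

    if "selection" in config.stages:
        t0 = time.time()
        if "wild_genes" not in state:
            raise StageError("selection", "missing upstream simulate outputs")
        sd = outdir / "selection"
        sd.mkdir(exist_ok=True)
        wild, cult = state["wild"], state["cult"]
        gene_sets = {
            "wild": {f"w_{g.id}": g.cds(wild) for g in state["wild_genes"]},
            "cultivar": {f"c_{g.id}": g.cds(cult) for g in state["cult_genes"]},
        }
        clusters = find_orthologues(gene_sets)
        records, class_counts = selection_scan(
            clusters, "wild", "cultivar", gene_sets, config.neutral_tolerance
        )
        formats.write_tsv(
            sd / "selection.tsv",
            pd.DataFrame(
                [
                    (r.cluster_id, r.gene_a, r.gene_b, round(r.ka, 6), round(r.ks, 6),
                     round(r.ratio, 4) if np.isfinite(r.ratio) else "NA", r.selection_class)
                    for r in records
                ],
                columns=["cluster", "gene_wild", "gene_cultivar", "ka", "ks", "ratio", "class"],
            ),
        )
        status_counts: dict[str, int] = {}
        for cl in clusters:
            s = cl.status(["wild", "cultivar"])
            status_counts[s] = status_counts.get(s, 0) + 1
        (sd / "selection.json").write_text(
            json.dumps({"classes": class_counts, "cluster_status": status_counts}, indent=2) + "\n"
        )
        state["clusters"] = clusters
        record("selection", t0)

    if "mite" in config.stages:
        t0 = time.time()
        if "wild_genes" not in state:
            raise StageError("mite", "missing upstream simulate outputs")
        sd = outdir / "mite"
        sd.mkdir(exist_ok=True)
        wild, cult = state["wild"], state["cult"]
        wregions = extract_upstream(state["wild_genes"], wild, "wild", config.window)
        cregions = extract_upstream(state["cult_genes"], cult, "cultivar", config.window)
        wins = detect_in_regions(wregions)
        cins = detect_in_regions(cregions)
        shared_genes = sorted(
            {g.id for g in state["wild_genes"]} & {g.id for g in state["cult_genes"]}
        )
        presence = compare_presence(
            [(g, g) for g in shared_genes],
            {r.gene_id: r for r in wregions},
            {r.gene_id: r for r in cregions},
            wins,
            cins,
            labels=("wild", "cultivar"),
        )
        formats.write_tsv(sd / "presence.tsv", presence)
        counts = state["counts"]
        groups = ["wild"] * sim.n_replicates + ["cultivar"] * sim.n_replicates
        de = diff_expression(counts, groups, alpha=config.alpha)
        formats.write_tsv(sd / "differential_expression.tsv", de, index=True)
        specific = sorted(
            set(presence[presence.label == "cultivar-specific"].gene_b)
        )
        summary = associate(specific, de, alpha=config.alpha)
        pval = association_permutation_pvalue(
            de, specific, stage_rng(seed, "other"), n_permutations=199
        )
        (sd / "association.json").write_text(json.dumps({
            "n_cultivar_specific": summary.n_specific,
            "n_lower": summary.n_lower,
            "n_higher": summary.n_higher,
            "frac_lower": round(summary.frac_lower, 4),
            "frac_higher": round(summary.frac_higher, 4),
            "alpha": summary.alpha,
            "permutation_p_lower_enrichment": pval,
        }, indent=2) + "\n")
        record("mite", t0)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
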