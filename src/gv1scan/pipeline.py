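"""End-to-end orchestration of the analysis chain on synthetic inputs.

Runs the stages in the study's order — linkage scan, depth-ratio CNV
profiling and clustering, alignment-segment analysis and scaffolding,
acceptor classification, differential ERV expression — writing per-stage
outputs plus a machine-readable JSON summary.  Deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from gv1scan import __version__, io, synthetic
from gv1scan.assembly import (
    duplicated_regions,
    filter_segments,
    join_scaffolds,
    query_unique_regions,
    reference_multiplicity,
)
from gv1scan.cnv import cluster_strains, depth_ratio, mae_matrix, segment_ratio
from gv1scan.expression import de_test, pbs_stratification, subclass_fold_summary
from gv1scan.linkage import linkage_scan
from gv1scan.splice import classify_acceptor, compare_acceptors

SUMMARY_SCHEMA_VERSION = 1

log = logging.getLogger("gv1scan")


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    outdir: str = "gv1scan_run"
    seed: int = 1
    window_bp: int = 10_000
    pseudocount: float = 0.5
    min_segment_bp: int = 1000
    min_segment_identity: float = 98.0
    q_threshold: float = 0.01
    lfc_threshold: float = 1.0
    n_animals: int = 1108
    penetrance: float = 0.95
    n_permutations: int = 10_000
    n_loci_per_class: int = 40
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.min_segment_bp < 0 or not 0 <= self.min_segment_identity <= 100:
            raise ValueError("segment thresholds out of range")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")

    def to_flat(self) -> dict:
        return {k: v for k, v in asdict(self).items()}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_flat().items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def read(cls, path) -> "RunConfig":
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r}")
                typ = {"int": int, "float": float, "str": str}[fields[k]]
                kwargs[k] = typ(v)
        return cls(**kwargs)


def run_pipeline(cfg: RunConfig) -> dict:
    """Generate synthetic inputs and run every stage; returns the summary."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cfg.seed,
    }

    stage = "linkage"
    try:
        log.info("stage %s", stage)
        bc = synthetic.gen_backcross(
            synthetic.default_backcross_markers(),
            synthetic.default_trait_pos_cm(),
            n_animals=cfg.n_animals,
            penetrance=cfg.penetrance,
            seed=cfg.seed,
        )
        io.write_backcross(bc, out / "marker_map.tsv", out / "genotypes.tsv")
        scan = linkage_scan(bc)
        scan.table.to_csv(out / "linkage.tsv", sep="\t", index=False)
        summary["linkage"] = {
            "peak_mb": round(scan.peak_mb, 4),
            "max_lod": round(float(scan.table["lod"].max()), 2),
            "peak_marker": scan.peak_marker,
        }

        stage = "cnv"
        log.info("stage %s", stage)
        specs = synthetic.default_strain_panel()
        sim = synthetic.SimConfig(
            region=synthetic.PANEL_REGION, window_bp=cfg.window_bp, seed=cfg.seed
        )
        profiles = synthetic.gen_depth_profiles(specs, sim)
        ref = profiles[0]
        ratios = [depth_ratio(p, ref, cfg.pseudocount) for p in profiles[1:]]
        calls = {rp.strain: segment_ratio(rp) for rp in ratios}
        all_calls = [c for cs in calls.values() for c in cs]
        io.write_cnv_calls(all_calls, out / "cnv_calls.tsv")
        dmat = mae_matrix([depth_ratio(p, ref, cfg.pseudocount) for p in profiles])
        io.write_distance_matrix(dmat, out / "mae_matrix.tsv")
        clust = cluster_strains(dmat, n_groups=2)
        summary["cnv"] = {
            "n_calls": len(all_calls),
            "deletion_spans_kb": sorted(
                round(c.span_kb, 1) for c in all_calls if c.state == "0"
            ),
            "cluster_groups": sorted(sorted(g) for g in clust.groups()),
        }

        stage = "assembly"
        log.info("stage %s", stage)
        dup = [(400_000, 500_000)]
        uniq = [(900_000, 1_000_000)]
        segs = synthetic.gen_alignment_segments(dup, uniq, seed=cfg.seed)
        io.write_paf(segs, out / "segments.paf")
        kept = filter_segments(segs, cfg.min_segment_bp, cfg.min_segment_identity)
        mult = reference_multiplicity(kept, cfg.window_bp)
        dups = duplicated_regions(mult, cfg.window_bp)
        qlen = max(s.qend for s in segs)
        unique = query_unique_regions(kept, {"assembly": qlen})
        io.write_bed(dups, out / "duplicated_regions.bed")
        io.write_bed(unique, out / "unique_regions.bed")
        clones, components = synthetic.gen_clone_sequences(
            [3, 2, 2, 2, 2, 1, 1, 2], seed=cfg.seed
        )
        io.write_fasta(clones, out / "clones.fa")
        scaffolds = join_scaffolds(clones)
        summary["assembly"] = {
            "n_segments_kept": len(kept),
            "n_duplicated_regions": len(dups),
            "n_unique_regions": len(unique),
            "n_clones": len(clones),
            "n_scaffolds": scaffolds.n_scaffolds,
            "true_components": len(components),
        }

        stage = "splice"
        log.info("stage %s", stage)
        sites = synthetic.gen_acceptor_sequences(seed=cfg.seed)
        ref_site = next(s for s in sites if s.label == "consensus")
        verdicts = []
        for s in sites:
            v = compare_acceptors(ref_site, s) if s is not ref_site else None
            cv = classify_acceptor(s)
            verdicts.append(
                dict(
                    label=s.label,
                    strand=s.strand,
                    passes=cv.passes,
                    impact=(v.impact if v else "none"),
                )
            )
        with open(out / "acceptor_verdicts.tsv", "w") as fh:
            fh.write("label\tstrand\tpasses\timpact\n")
            for v in verdicts:
                fh.write(f"{v['label']}\t{v['strand']}\t{v['passes']}\t{v['impact']}\n")
        summary["splice"] = {
            "n_sites": len(verdicts),
            "n_pass": sum(v["passes"] for v in verdicts),
            "n_high_impact": sum(v["impact"] == "high" for v in verdicts),
        }

        stage = "expression"
        log.info("stage %s", stage)
        n = cfg.n_loci_per_class
        m = synthetic.gen_expression_counts(
            n_loci_per_class={"eMLV": n, "mpMLV": n, "pMLV": n, "xMLV": n},
            fold_changes={"pMLV": 14.5, "xMLV": 5.3},
            n_per_group=3,
            seed=cfg.seed,
        )
        io.write_expression(m, out / "counts.tsv", out / "groups.tsv")
        de = de_test(m, n_permutations=cfg.n_permutations, seed=cfg.seed,
                     q_threshold=cfg.q_threshold, lfc_threshold=cfg.lfc_threshold)
        de.table.to_csv(out / "de_results.tsv", sep="\t")
        folds = subclass_fold_summary(de, m)
        pbs = pbs_stratification(de, m)
        summary["expression"] = {
            "n_regulated": int(de.table["regulated"].sum()),
            "subclass_mean_fold": {k: round(v, 2) for k, v in folds.items()},
            "pbs_p_value": round(pbs.p_value, 4),
            "pbs_stratified": pbs.stratified,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("summary written to %s", out / "summary.json")
    return summary
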