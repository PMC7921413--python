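"""Pipeline configuration and the end-to-end driver.

Stage defaults mirror the method's published operating point: sites need 5
reads in 20 cells; a cell is mutant-called at 10% minor-allele fraction;
candidates need 1% of a patient's cells and at most 10 mutant cells in any
other individual; call-matrix variants need coverage in 20% of cells and a
5% VAF cutoff; the tree model uses dropout 0.10 and false-positive rate
0.03; robustness uses 80 Latin-hypercube runs at concentration 10; clones
merge below an average swap cost of 1 per cell; cells are assigned at 0.8
posterior confidence; de novo candidates need a mean above 20 reads/cell.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs
    counts: dict[str, str] = field(default_factory=dict)  # individual -> count-table TSV
    individual: str | None = None  # focal individual for tree inference (default: first)
    candidates: str | None = None  # de novo candidate sites TSV
    germline_exclusions: str | None = None  # TSV with contig, position, alt
    outdir: str = "clonetrace_out"
    # cohort filter
    min_reads: int = 5
    min_cells: int = 20
    min_cell_vaf: float = 0.10
    min_fraction_in_patient: float = 0.01
    max_cells_other: int = 10
    # call matrix
    min_covered_fraction: float = 0.20
    vaf_cutoff: float = 0.05
    # tree model
    alpha: float = 0.10
    beta: float = 0.03
    estimate_alpha: bool = True
    max_exhaustive: int = 7
    n_restarts: int = 20
    # robustness
    run_robustness: bool = False
    robustness_runs: int = 80
    concentration: float = 10.0
    # clones
    swap_threshold_per_cell: float = 1.0
    min_confidence: float = 0.8
    # de novo
    min_mean_reads: float = 20.0
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute count loading -> cohort filter -> matrix -> tree -> clones ->
    assignment -> de novo scan, writing every artifact under ``outdir``.

    Returns the in-memory artifact bundle. Any stage failure raises a
    RuntimeError naming the stage.
    """
    from . import callmatrix, clones, cohort, counts, denovo, tree

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": config.config_hash()}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    @stage("load-counts")
    def tables():
        if not config.counts:
            raise ValueError("no count tables configured")
        return {
            ind: counts.read_count_table(path, individual_id=ind)
            for ind, path in sorted(config.counts.items())
        }

    @stage("filter-cohort")
    def filtered():
        cands, blacklist = cohort.discover_cohort_variants(
            tables,
            min_reads=config.min_reads,
            min_cells=config.min_cells,
            min_cell_vaf=config.min_cell_vaf,
            min_fraction_in_patient=config.min_fraction_in_patient,
            max_cells_other=config.max_cells_other,
        )
        blacklist.to_tsv(outdir / "blacklist.tsv")
        cohort.write_candidates(cands, outdir / "candidate_variants.tsv")
        return cands, blacklist

    candidates_by_ind, blacklist = filtered
    focal = config.individual or sorted(tables)[0]
    table = tables[focal]
    bundle.update(tables=tables, blacklist=blacklist, candidates=candidates_by_ind)

    @stage("build-matrix")
    def matrix():
        selected = callmatrix.select_covered_variants(
            table, candidates_by_ind[focal], min_cell_fraction=config.min_covered_fraction
        )
        m = callmatrix.build_call_matrix(table, selected, vaf_cutoff=config.vaf_cutoff)
        m.to_tsv(outdir / "call_matrix.tsv")
        m.counts_to_tsv(outdir / "call_counts.tsv")
        return m

    @stage("infer-tree")
    def fitted():
        if config.estimate_alpha:
            alpha = tree.estimate_dropout_per_variant(matrix)
        else:
            alpha = config.alpha
        model = tree.NoiseModel(alpha=alpha, beta=config.beta)
        t = tree.infer_tree(
            matrix, model, max_exhaustive=config.max_exhaustive,
            n_restarts=config.n_restarts, seed=config.seed,
        )
        payload = t.to_dict()
        payload["config_hash"] = config.config_hash()
        (outdir / "tree.json").write_text(json.dumps(payload, indent=2))
        (outdir / "tree.nwk").write_text(t.newick() + "\n")
        return t, model

    inferred_tree, model = fitted

    @stage("cluster-clones")
    def clone_structure():
        cs = clones.cluster_metaclones(
            inferred_tree, matrix, model, threshold_per_cell=config.swap_threshold_per_cell
        )
        cs.to_tsv(outdir / "clones.tsv")
        return cs

    @stage("assign-cells")
    def assignment():
        a = clones.assign_cells(matrix, clone_structure, model, min_confidence=config.min_confidence)
        a.to_tsv(outdir / "assignments.tsv")
        return a

    bundle.update(matrix=matrix, tree=inferred_tree, model=model,
                  clones=clone_structure, assignment=assignment)

    if config.run_robustness:
        @stage("robustness")
        def robustness():
            alpha_means = tree.estimate_dropout_per_variant(matrix)
            res = tree.robustness_analysis(
                matrix, alpha_means, beta=config.beta,
                concentration=config.concentration, n_runs=config.robustness_runs,
                seed=config.seed, max_exhaustive=config.max_exhaustive,
                n_restarts=config.n_restarts,
                clone_threshold_per_cell=config.swap_threshold_per_cell,
            )
            (outdir / "robustness.json").write_text(json.dumps(
                {"n_runs": config.robustness_runs, "n_agreeing_runs": res.n_agreeing_runs}
            ))
            return res

        bundle["robustness"] = robustness

    if config.candidates:
        @stage("denovo")
        def denovo_results():
            cand = denovo.CandidateSiteList.from_tsv(config.candidates)
            excl = []
            if config.germline_exclusions:
                import pandas as pd

                edf = pd.read_csv(config.germline_exclusions, sep="\t",
                                  dtype={"contig": str, "alt": str})
                excl = [(r.contig, int(r.position), r.alt) for r in edf.itertuples()]
            cand = denovo.filter_candidate_sites(
                table, cand, germline_exclusions=excl, min_mean_reads=config.min_mean_reads
            )
            clone_of_cell = dict(zip(assignment.cells, assignment.best_clone))
            assigned = [c for c, ok in zip(assignment.cells, assignment.assigned) if ok]
            df = denovo.scan_sites(table, cand, clone_of_cell, assigned_cells=assigned)
            df.to_csv(outdir / "denovo.tsv", sep="\t", index=False)
            return df

        bundle["denovo"] = denovo_results

    logger.info("pipeline complete; artifacts in %s (config %s)", outdir, bundle["config_hash"])
    return bundle
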