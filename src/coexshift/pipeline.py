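"""End-to-end pipeline: load, collapse, subset, correlate, cut, classify, map.

Artifacts are written in a fixed order with deterministic content (no
timestamps), so rerunning on identical inputs reproduces the outputs
byte for byte:

    collapsed_matrix.tsv   gene-level matrix after probe averaging
    pairs.tsv              per-pair |r| in each group
    cutoff.json            D, C, p-value, pair counts, tie information
    classification.tsv     per-pair class at the cutoff
    mapping_<category>.tsv one per annotation category (term, a..d, p, ...)
    run.log                versions, inputs, thresholds, stage summaries
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from coexshift.classify import classify_pairs, strong_proportion_test
from coexshift.coexpress import pairwise_abs_pearson
from coexshift.cutoff import deviation_curve, ks_cutoff
from coexshift.expression_io import (
    ExpressionMatrix,
    collapse_probes,
    load_design,
    load_expression,
    load_gene_list,
    load_probe_map,
    subset_to_genes,
)
from coexshift.go_mapping import map_all_terms, read_annotation, results_to_frame


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one reproducible pipeline run."""

    expression: Path
    design: Path
    out_dir: Path
    genes: Path | None = None
    probe_map: Path | None = None
    annotations: dict[str, Path] = field(default_factory=dict)  # category -> file
    expression_format: str = "tsv"
    zero_var: str = "error"
    cap_corrected_p: bool = False
    alpha: float = 0.05
    missing: str = "reject"

    def __post_init__(self):
        for name in ("expression", "design", "genes", "probe_map"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise PipelineError(f"config: {name} path does not exist: {p}")
        self.annotations = {k: Path(v) for k, v in self.annotations.items()}
        for cat, p in self.annotations.items():
            if not p.exists():
                raise PipelineError(f"config: annotation '{cat}' path does not exist: {p}")
        if not 0 < self.alpha < 1:
            raise PipelineError(f"config: alpha must be in (0, 1), got {self.alpha}")
        self.out_dir = Path(self.out_dir)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("load")
def _load(config: RunConfig) -> ExpressionMatrix:
    probe = load_expression(config.expression, format=config.expression_format)
    groups = load_design(config.design)
    probe_map = load_probe_map(config.probe_map) if config.probe_map else None
    if probe_map is None and probe.probe_to_gene is None:
        # already gene-level: collapse with the identity map (a no-op average)
        probe_map = {p: p for p in probe.values.index}
    return collapse_probes(probe, probe_map, groups=groups, missing=config.missing)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the artifact set to ``config.out_dir``.

    Returns a summary dict with the cutoff result, class counts and the
    per-category mapping frames.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    import coexshift

    log(f"coexshift version: {coexshift.__version__}")
    log(f"expression: {config.expression} (format={config.expression_format})")
    log(f"design: {config.design}")
    log(f"zero_var={config.zero_var} cap_corrected_p={config.cap_corrected_p} "
        f"alpha={config.alpha} missing={config.missing}")

    matrix = _load(config)
    log(f"loaded matrix: {matrix.n_genes} genes x {len(matrix.sample_ids)} samples "
        f"({len(matrix.samples_of('disease'))} disease, {len(matrix.samples_of('normal'))} normal)")

    if config.genes is not None:
        sub = _stage("subset")(subset_to_genes)(matrix, load_gene_list(config.genes))
        matrix = sub.matrix
        log(f"candidate genes: {sub.n_found} found, {sub.n_missing} missing")
    matrix.values.to_csv(out / "collapsed_matrix.tsv", sep="\t", float_format="%.10g")

    pc = _stage("coexpress")(pairwise_abs_pearson)(matrix, zero_var=config.zero_var)
    pc.to_tsv(out / "pairs.tsv")
    log(f"pairs: {pc.n_pairs} per group")

    result = _stage("cutoff")(ks_cutoff)(pc)
    result.to_json(out / "cutoff.json")
    deviation_curve(pc.c_disease, pc.c_normal).to_csv(
        out / "deviation_curve.tsv", sep="\t", index=False, float_format="%.10g"
    )
    log(f"cutoff: D={result.D:.6g} C={result.C:.6g} p={result.p_value:.6g}")
    log(f"cutoff tie-break: {result.tie_count} threshold(s) attained D; smallest returned")

    classes = _stage("classify")(classify_pairs)(pc, result.C)
    classes.to_tsv(out / "classification.tsv")
    log(
        "classes: normal %d strong / %d weak; disease %d strong / %d weak"
        % (classes.n_strong_normal, classes.n_weak_normal,
           classes.n_strong_disease, classes.n_weak_disease)
    )
    prop_p = strong_proportion_test(
        classes.n_strong_disease, pc.n_pairs, classes.n_strong_normal, pc.n_pairs
    )
    log(f"strong-proportion one-sided p: {prop_p:.6g}")

    mappings = {}
    for category, path in sorted(config.annotations.items()):
        annotation = _stage(f"map-go[{category}]")(read_annotation)(path)
        results = _stage(f"map-go[{category}]")(map_all_terms)(
            annotation, classes, cap_at_1=config.cap_corrected_p
        )
        frame = results_to_frame(results)
        frame.to_csv(out / f"mapping_{category}.tsv", sep="\t", index=False,
                     float_format="%.10g")
        mappings[category] = frame
        log(f"mapping[{category}]: {len(results)} terms, "
            f"{int(frame['significant'].sum())} significant")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "matrix": matrix,
        "pairs": pc,
        "cutoff": result,
        "classes": classes,
        "strong_proportion_p": prop_p,
        "mappings": mappings,
    }
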