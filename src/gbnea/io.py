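"""Readers/writers for the interchange formats and the pipeline driver.

Formats are deliberately plain text: expression matrices and phenotype maps
as TSV, gene sets as GMT, networks as canonical edge-list TSV (sorted by
regulator then target so written files diff reproducibly), run
configurations as YAML/JSON.  Every writer's output is re-readable by the
corresponding reader.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import BehaviorScores, behavior_scores
from .enrichment import GeneSetCollection
from .exceptions import DataValidationError, PipelineStageError
from .network import (DirectedNetwork, ExpressionDataset, RegressionConfig,
                      estimate_network)
from .permutation import EnrichmentAnalysis, PermutationConfig, run_enrichment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression and phenotypes
# ---------------------------------------------------------------------------

def read_expression(path) -> tuple[np.ndarray, tuple[str, ...],
                                   tuple[str, ...]]:
    """Expression TSV -> (values, gene_ids, sample_ids).

    First column holds gene identifiers; the header row holds sample
    identifiers.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty and frame.columns.empty:
        raise DataValidationError(f"{path}: empty expression file")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataValidationError(
            f"{path}: non-numeric expression values ({exc})") from None
    return (values, tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)))


def write_expression(path, values: np.ndarray, gene_ids, sample_ids) -> None:
    frame = pd.DataFrame(values, index=list(gene_ids),
                         columns=list(sample_ids))
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_phenotypes(path) -> dict[str, str]:
    """Two-column TSV (sample identifier, phenotype label) -> mapping."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise DataValidationError(
            f"{path}: expected two tab-separated columns (sample, phenotype)")
    samples = frame.iloc[:, 0].astype(str)
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise DataValidationError(f"{path}: duplicate sample {dup!r}")
    return dict(zip(samples, frame.iloc[:, 1].astype(str)))


def write_phenotypes(path, sample_ids, phenotype) -> None:
    pd.DataFrame({"sample": list(sample_ids),
                  "phenotype": list(phenotype)}
                 ).to_csv(path, sep="\t", index=False)


def load_expression_dataset(expression_path, phenotype_path,
                            ) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from the two TSV files."""
    values, gene_ids, sample_ids = read_expression(expression_path)
    pheno_map = read_phenotypes(phenotype_path)
    missing = [s for s in sample_ids if s not in pheno_map]
    if missing:
        raise DataValidationError(
            f"phenotype label missing for sample(s) {missing[:5]}")
    phenotype = tuple(pheno_map[s] for s in sample_ids)
    return ExpressionDataset(values, gene_ids, sample_ids, phenotype)


def write_dataset(directory, data: ExpressionDataset,
                  prefix: str = "expression") -> tuple[Path, Path]:
    directory = Path(directory)
    expr = directory / f"{prefix}.tsv"
    pheno = directory / f"{prefix}_phenotypes.tsv"
    write_expression(expr, data.values, data.gene_ids, data.sample_ids)
    write_phenotypes(pheno, data.sample_ids, data.phenotype)
    return expr, pheno


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """GMT file -> gene-set collection.

    Standard dialect: one set per line, tab-separated name, description,
    then member genes; duplicate members collapse; a line with fewer than
    two fields or with no members is rejected with its line number.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataValidationError(
                    f"{path}:{lineno}: malformed GMT line "
                    "(need name, description, members)")
            name = fields[0].strip()
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                raise DataValidationError(
                    f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise DataValidationError(
                    f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
    if not sets:
        warnings.warn(f"{path}: empty GMT file, no gene sets loaded")
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(path, gene_sets: GeneSetCollection,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets:
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# networks (edge-list TSV)
# ---------------------------------------------------------------------------

_EDGE_HEADER = "regulator\ttarget\tweight\tphenotype"


def write_network_edgelist(path, network: DirectedNetwork) -> None:
    """Canonical edge-list TSV (sorted by regulator, then target).

    The gene universe (including isolated genes) and the phenotype label are
    preserved in comment lines so the file round-trips losslessly.
    """
    with open(path, "w") as fh:
        fh.write(f"# genes: {','.join(network.gene_ids)}\n")
        if network.phenotype_label is not None:
            fh.write(f"# phenotype: {network.phenotype_label}\n")
        fh.write(_EDGE_HEADER + "\n")
        label = network.phenotype_label or ""
        for (reg, tgt) in sorted(network.coefficients):
            w = network.coefficients[(reg, tgt)]
            fh.write(f"{reg}\t{tgt}\t{w!r}\t{label}\n")


def read_network_edgelist(path) -> DirectedNetwork:
    """Edge-list TSV -> network; zero weights, self-edges and duplicate
    (regulator, target) rows are rejected with their row number."""
    gene_ids: tuple[str, ...] | None = None
    phenotype: str | None = None
    coefficients: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("genes:"):
                    gene_ids = tuple(
                        g.strip() for g in body[len("genes:"):].split(",")
                        if g.strip())
                elif body.startswith("phenotype:"):
                    phenotype = body[len("phenotype:"):].strip() or None
                continue
            if line.startswith("regulator\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: expected regulator, target, weight")
            reg, tgt = fields[0].strip(), fields[1].strip()
            try:
                w = float(fields[2])
            except ValueError:
                raise DataValidationError(
                    f"{path}:{lineno}: non-numeric weight "
                    f"{fields[2]!r}") from None
            if reg == tgt:
                raise DataValidationError(
                    f"{path}:{lineno}: self-edge on {reg!r}")
            if w == 0:
                raise DataValidationError(
                    f"{path}:{lineno}: zero-weight edge ({reg}, {tgt})")
            if (reg, tgt) in coefficients:
                raise DataValidationError(
                    f"{path}:{lineno}: duplicate edge ({reg}, {tgt})")
            if len(fields) >= 4 and fields[3].strip():
                phenotype = phenotype or fields[3].strip()
            coefficients[(reg, tgt)] = w
    if gene_ids is None:
        endpoint = sorted({g for e in coefficients for g in e})
        gene_ids = tuple(endpoint)
    return DirectedNetwork(gene_ids, coefficients, phenotype)


# ---------------------------------------------------------------------------
# scores, running sums, results
# ---------------------------------------------------------------------------

def write_scores(path, scores: BehaviorScores) -> None:
    scores.to_frame().to_csv(path, sep="\t", index=False)


def write_running_sums(path, analysis: EnrichmentAnalysis) -> None:
    """Per-pathway running-sum curves as TSV (position x pathway)."""
    columns = {"position": np.arange(1, len(analysis.ranking.order) + 1),
               "gene": analysis.ranking.order}
    for name, res in analysis.score_results.items():
        columns[name] = res.running_sum
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)


def write_results(path, analysis: EnrichmentAnalysis, alpha: float) -> None:
    frame = analysis.to_frame()
    frame[f"significant({alpha:g})"] = frame.pop("significant")
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    expression_path: str
    phenotype_path: str
    gmt_path: str
    labels: tuple[str, str] = ("C", "N")
    stat_name: str = "Wd1"
    k: float = 0.0
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    output_dir: str = "gbnea_output"
    log_level: str = "INFO"

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != 2 or self.labels[0] == self.labels[1]:
            raise DataValidationError(
                "labels must name two distinct phenotypes")


def load_run_config(path) -> RunConfig:
    """RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") \
        else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise DataValidationError(f"{path}: expected a mapping")
    reg = RegressionConfig(**raw.pop("regression", {}))
    perm = PermutationConfig(**raw.pop("permutation", {}))
    if "labels" in raw:
        raw["labels"] = tuple(raw["labels"])
    try:
        return RunConfig(regression=reg, permutation=perm, **raw)
    except TypeError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def run_pipeline(config: RunConfig) -> EnrichmentAnalysis:
    """Execute the full analysis described by ``config`` and write artifacts.

    Writes both phenotype networks, the behavior scores, the per-pathway
    running sums and the result table into ``config.output_dir``.  A stage
    failure leaves an ``INCOMPLETE`` marker file naming the failed stage and
    re-raises with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("pipeline starting\n")

    import gbnea

    logger.info("gbnea %s | numpy %s | seed %d | stat %s | k %g | "
                "delta %g | n_perm %d | alpha %g",
                gbnea.__version__, np.__version__, config.permutation.seed,
                config.stat_name, config.k, config.regression.delta,
                config.permutation.n_perm, config.permutation.alpha)

    stage = "load-inputs"
    try:
        marker.write_text(f"incomplete: running stage {stage}\n")
        data = load_expression_dataset(config.expression_path,
                                       config.phenotype_path)
        gene_sets = read_gmt(config.gmt_path)
        for label in config.labels:
            if label not in data.phenotype_levels():
                raise DataValidationError(
                    f"label {label!r} absent from phenotype file")

        stage = "enrichment-analysis"
        marker.write_text(f"incomplete: running stage {stage}\n")
        analysis = run_enrichment(
            data, gene_sets, labels=config.labels,
            stat_name=config.stat_name, k=config.k,
            reg_config=config.regression, perm_config=config.permutation)

        stage = "write-outputs"
        marker.write_text(f"incomplete: running stage {stage}\n")
        write_network_edgelist(out / "network_C.tsv", analysis.network_C)
        write_network_edgelist(out / "network_N.tsv", analysis.network_N)
        write_scores(out / "scores.tsv", analysis.scores)
        write_running_sums(out / "running_sums.tsv", analysis)
        write_results(out / "results.tsv", analysis,
                      config.permutation.alpha)
        (out / "run_config.json").write_text(json.dumps(
            dataclasses.asdict(config), indent=2, default=str) + "\n")
    except Exception as exc:
        marker.write_text(f"incomplete: failed at stage {stage}: {exc}\n")
        raise PipelineStageError(stage, str(exc)) from exc
    marker.unlink()
    return analysis


def score_networks_cli_helper(net_c_path, net_n_path, expression_path,
                              phenotype_path) -> BehaviorScores:
    """Scores from previously written networks plus the expression files."""
    net_c = read_network_edgelist(net_c_path)
    net_n = read_network_edgelist(net_n_path)
    data = load_expression_dataset(expression_path, phenotype_path)
    label_c = net_c.phenotype_label or "C"
    label_n = net_n.phenotype_label or "N"
    if net_c.gene_ids != net_n.gene_ids:
        raise DataValidationError(
            "the two networks must share one gene universe")
    index = {g: i for i, g in enumerate(data.gene_ids)}
    missing = [g for g in net_c.gene_ids if g not in index]
    if missing:
        raise DataValidationError(
            f"expression data lacks network gene(s) {missing[:5]}")
    rows = [index[g] for g in net_c.gene_ids]
    mean_c = data.mean_expression(label_c)[rows]
    mean_n = data.mean_expression(label_n)[rows]
    return behavior_scores(net_c, net_n, mean_c, mean_n)
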