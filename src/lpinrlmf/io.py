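"""Readers/writers for the on-disk formats, configuration, and the pipeline.

Formats are deliberately plain: interactions as a two-column TSV of
(lncRNA id, protein id) pairs, similarity and score matrices as TSV with
ids on the first row and column (similarities written with 6 decimals so
write-then-read round-trips at the declared precision), FASTA for
sequences, YAML for run configuration, JSON for the model bundle and the
run manifest.  All writers go through an atomic ``.partial`` -> rename step
so an interrupted run never leaves a file that looks complete.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .evaluation import EvaluationReport, loocv
from .exceptions import InputError, ParseError, PipelineError
from .kernels import (
    NUCLEOTIDE,
    PROTEIN,
    AlignmentScoring,
    SequenceRecord,
    SimilarityMatrix,
    default_scoring,
    normalized_similarity_matrix,
)
from .model import Hyperparameters, InteractionMatrix, LatentModel, ScoreMatrix, fit, predict

logger = logging.getLogger("lpinrlmf")

#: header sentinels recognized on the first line of an interaction TSV
_HEADER_SENTINELS = {
    ("lncrna", "protein"),
    ("lncrna_id", "protein_id"),
    ("lnc", "prot"),
    ("lncrna id", "protein id"),
}

_SIM_DECIMALS = 6


def configure_logging(level: str = "INFO"):
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


class atomic_write:
    """Write to ``<path>.partial`` and rename on success, so failures never
    leave a file without the ``.partial`` marker."""

    def __init__(self, path):
        self.path = Path(path)
        self.partial = self.path.with_name(self.path.name + ".partial")

    def __enter__(self):
        self._fh = open(self.partial, "w")
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self.partial, self.path)
        return False


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def read_interactions(path) -> InteractionMatrix:
    """Parse a two-column TSV of known (lncRNA, protein) pairs.

    Ids are deduplicated preserving first-appearance order; duplicate pairs
    collapse to a single 1 with a logged warning; blank lines are ignored;
    a line with other than two fields is a parse error naming the line.
    """
    path = Path(path)
    lnc_ids: list[str] = []
    prot_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    seen_pairs = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"expected 2 tab-separated fields, got {len(fields)}", line=lineno
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ParseError("empty identifier", line=lineno)
            if lineno == 1 and (a.lower(), b.lower()) in _HEADER_SENTINELS:
                continue
            if (a, b) in seen_pairs:
                n_dup += 1
                continue
            seen_pairs.add((a, b))
            if a not in lnc_ids:
                lnc_ids.append(a)
            if b not in prot_ids:
                prot_ids.append(b)
            pairs.append((a, b))
    if not pairs:
        raise InputError(f"no interactions found in {path}")
    if n_dup:
        logger.warning("collapsed %d duplicate interaction pairs", n_dup)
    Y = np.zeros((len(lnc_ids), len(prot_ids)))
    li = {x: i for i, x in enumerate(lnc_ids)}
    pi = {x: j for j, x in enumerate(prot_ids)}
    for a, b in pairs:
        Y[li[a], pi[b]] = 1.0
    return InteractionMatrix(lncrna_ids=lnc_ids, protein_ids=prot_ids, Y=Y)


def write_interactions(Y: InteractionMatrix, path):
    with atomic_write(path) as fh:
        for i, j in Y.positive_pairs():
            fh.write(f"{Y.lncrna_ids[i]}\t{Y.protein_ids[j]}\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(ids_rows, ids_cols, values, path, decimals=_SIM_DECIMALS):
    with atomic_write(path) as fh:
        fh.write("id\t" + "\t".join(ids_cols) + "\n")
        for rid, row in zip(ids_rows, np.asarray(values)):
            fh.write(rid + "\t" + "\t".join(f"{x:.{decimals}f}" for x in row) + "\n")


def write_similarity(S: SimilarityMatrix, path):
    write_matrix(S.ids, S.ids, S.values, path)


def write_scores(scores: ScoreMatrix, path):
    write_matrix(scores.lncrna_ids, scores.protein_ids, scores.values, path)


def write_ranked_pairs(scores: ScoreMatrix, path, exclude: Optional[InteractionMatrix] = None):
    """Long-format (lncRNA, protein, score, rank) list, descending score.

    ``exclude`` drops the known positives so the list ranks novel candidates.
    """
    rows = []
    for i, lid in enumerate(scores.lncrna_ids):
        for j, pid in enumerate(scores.protein_ids):
            if exclude is not None and exclude.Y[i, j] == 1:
                continue
            rows.append((lid, pid, scores.values[i, j]))
    rows.sort(key=lambda t: (-t[2], t[0], t[1]))
    with atomic_write(path) as fh:
        fh.write("lncrna\tprotein\tscore\trank\n")
        for rank, (lid, pid, s) in enumerate(rows, start=1):
            fh.write(f"{lid}\t{pid}\t{s:.{_SIM_DECIMALS}f}\t{rank}\n")


def read_similarity(path) -> SimilarityMatrix:
    """Read a square TSV similarity matrix with matching row/column ids.

    Mild asymmetry (within 1e-6) is repaired by averaging with a warning;
    anything worse, an id mismatch, or out-of-range entries are errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_ids = header[1:]
        row_ids = []
        rows = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(col_ids) + 1:
                raise ParseError(
                    f"expected {len(col_ids) + 1} fields, got {len(fields)}",
                    line=lineno,
                )
            row_ids.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as e:
                raise ParseError(str(e), line=lineno) from e
    if row_ids != col_ids:
        raise InputError(f"row ids do not match column ids in {path}")
    values = np.array(rows)
    if values.min() < 0 or values.max() > 1:
        raise InputError(f"similarity entries outside [0, 1] in {path}")
    asym = np.abs(values - values.T).max()
    if asym > 1e-6:
        raise InputError(f"similarity matrix asymmetric beyond tolerance ({asym:.2e})")
    if asym > 0:
        logger.warning("symmetrized similarity matrix (max asymmetry %.2e)", asym)
        values = (values + values.T) / 2.0
    if np.abs(np.diag(values) - 1.0).max() > 1e-6:
        raise InputError(f"similarity diagonal must equal 1 in {path}")
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=row_ids, values=values)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str) -> list[SequenceRecord]:
    """Standard multi-record FASTA; the id is the description line
    truncated at the first whitespace."""
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq), alphabet=alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path):
    with atomic_write(path) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# model bundle (text JSON; Python float repr round-trips bit-exactly)
# ---------------------------------------------------------------------------

def save_model(model: LatentModel, path):
    bundle = {
        "format": "lpinrlmf-model",
        "version": __version__,
        "hyperparameters": dataclasses.asdict(model.hyperparameters),
        "lncrna_ids": model.lncrna_ids,
        "protein_ids": model.protein_ids,
        "U": [[repr(float(x)) for x in row] for row in model.U],
        "V": [[repr(float(x)) for x in row] for row in model.V],
        "S_l": {"ids": model.S_l.ids, "values": [[repr(float(x)) for x in row] for row in model.S_l.values]},
        "S_p": {"ids": model.S_p.ids, "values": [[repr(float(x)) for x in row] for row in model.S_p.values]},
        "training_history": [repr(float(x)) for x in model.training_history],
    }
    with atomic_write(path) as fh:
        json.dump(bundle, fh, indent=1)


def load_model(path) -> LatentModel:
    from .model import build_neighborhood  # local import to avoid cycle noise

    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("format") != "lpinrlmf-model":
        raise InputError(f"{path} is not a model bundle")
    hp = Hyperparameters(**bundle["hyperparameters"])
    U = np.array([[float(x) for x in row] for row in bundle["U"]])
    V = np.array([[float(x) for x in row] for row in bundle["V"]])
    S_l = SimilarityMatrix(
        bundle["S_l"]["ids"],
        np.array([[float(x) for x in row] for row in bundle["S_l"]["values"]]),
    )
    S_p = SimilarityMatrix(
        bundle["S_p"]["ids"],
        np.array([[float(x) for x in row] for row in bundle["S_p"]["values"]]),
    )
    return LatentModel(
        U=U,
        V=V,
        hyperparameters=hp,
        lncrna_ids=bundle["lncrna_ids"],
        protein_ids=bundle["protein_ids"],
        S_l=S_l,
        S_p=S_p,
        graph_l=build_neighborhood(S_l, hp.K1),
        graph_p=build_neighborhood(S_p, hp.K1),
        training_history=[float(x) for x in bundle["training_history"]],
    )


# ---------------------------------------------------------------------------
# degree filtering
# ---------------------------------------------------------------------------

def filter_entities(Y: InteractionMatrix, min_degree: int = 2) -> InteractionMatrix:
    """Iteratively remove lncRNAs and proteins with fewer than
    ``min_degree`` interactions until a fixed point (removing one side can
    drop the other side's degrees below the bar, so a single pass is not
    enough).  ``min_degree=2`` reproduces the standard LOOCV curation rule:
    an entity needs at least two interactions for every fold to retain one.
    """
    if min_degree < 1:
        raise InputError("min_degree must be >= 1")
    keep_l = np.arange(len(Y.lncrna_ids))
    keep_p = np.arange(len(Y.protein_ids))
    M = Y.Y
    while True:
        row_deg = M.sum(axis=1)
        col_deg = M.sum(axis=0)
        rows_ok = row_deg >= min_degree
        cols_ok = col_deg >= min_degree
        if rows_ok.all() and cols_ok.all():
            break
        keep_l = keep_l[rows_ok]
        keep_p = keep_p[cols_ok]
        M = M[np.ix_(rows_ok, cols_ok)]
        if M.size == 0:
            raise InputError(
                f"degree filter (min_degree={min_degree}) removed every entity"
            )
    return InteractionMatrix(
        lncrna_ids=[Y.lncrna_ids[i] for i in keep_l],
        protein_ids=[Y.protein_ids[j] for j in keep_p],
        Y=M.copy(),
    )


def align_similarity(S: SimilarityMatrix, ids: list[str]) -> SimilarityMatrix:
    """Reindex a similarity matrix to the given id order (subset allowed)."""
    missing = [x for x in ids if x not in S.ids]
    if missing:
        raise InputError(f"similarity matrix lacks ids: {missing[:10]}")
    idx = [S.index_of(x) for x in ids]
    return SimilarityMatrix(ids=list(ids), values=S.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration for the end-to-end pipeline."""

    interactions: Optional[Path] = None
    output_dir: Optional[Path] = None
    lnc_fasta: Optional[Path] = None
    prot_fasta: Optional[Path] = None
    lnc_sim: Optional[Path] = None
    prot_sim: Optional[Path] = None
    min_degree: int = 2
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    nucleotide_scoring: AlignmentScoring = field(
        default_factory=lambda: default_scoring(NUCLEOTIDE)
    )
    protein_scoring: AlignmentScoring = field(
        default_factory=lambda: default_scoring(PROTEIN)
    )
    run_loocv: bool = True
    fast_loocv: bool = False
    threshold: Optional[float] = None
    log_level: str = "INFO"

    def validate(self):
        if self.interactions is None or not Path(self.interactions).exists():
            raise InputError(f"interactions file not found: {self.interactions}")
        if self.output_dir is None:
            raise InputError("output_dir is required")
        for name in ("lnc_fasta", "prot_fasta", "lnc_sim", "prot_sim"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InputError(f"{name} not found: {p}")
        if self.lnc_fasta is None and self.lnc_sim is None:
            raise InputError("need lnc_fasta or lnc_sim")
        if self.prot_fasta is None and self.prot_sim is None:
            raise InputError("need prot_fasta or prot_sim")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    hp = Hyperparameters(**raw.get("hyperparameters", {}))
    nsc = raw.get("nucleotide_scoring", {})
    psc = raw.get("protein_scoring", {})
    kwargs = {
        k: v
        for k, v in raw.items()
        if k not in ("hyperparameters", "nucleotide_scoring", "protein_scoring")
    }
    for key in ("interactions", "output_dir", "lnc_fasta", "prot_fasta", "lnc_sim", "prot_sim"):
        if kwargs.get(key) is not None:
            kwargs[key] = Path(kwargs[key])
    return RunConfig(
        hyperparameters=hp,
        nucleotide_scoring=AlignmentScoring(alphabet=NUCLEOTIDE, **nsc),
        protein_scoring=AlignmentScoring(alphabet=PROTEIN, **psc),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _write_report(report: EvaluationReport, out_dir: Path):
    with atomic_write(out_dir / "pair_scores.tsv") as fh:
        fh.write("lncrna\tprotein\tlabel\tscore\n")
        for lid, pid, label, score in report.pair_scores:
            fh.write(f"{lid}\t{pid}\t{label}\t{score:.{_SIM_DECIMALS}f}\n")
    with atomic_write(out_dir / "summary.txt") as fh:
        fh.write(f"folds: {report.n_folds}\n")
        fh.write(f"AUC: {report.auc:.6f}\n")
        fh.write(f"AUPR: {report.aupr:.6f}\n")
        fh.write(f"threshold: {report.threshold:.6f}\n")
        fh.write(f"ACC: {report.metrics.ACC:.6f}\n")
        fh.write(f"SEN: {report.metrics.SEN:.6f}\n")
        fh.write(f"PRE: {report.metrics.PRE:.6f}\n")
        fh.write(f"F1: {report.metrics.F1:.6f}\n")
        if report.metrics.undefined:
            fh.write(f"undefined_metrics: {','.join(report.metrics.undefined)}\n")
    for name, pts, cols in (
        ("roc.tsv", report.roc_points, ("fpr", "tpr")),
        ("pr.tsv", report.pr_points, ("recall", "precision")),
    ):
        with atomic_write(out_dir / name) as fh:
            fh.write("\t".join(cols) + "\n")
            for a, b in pts:
                fh.write(f"{a:.6f}\t{b:.6f}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Similarity construction (or loading), degree filtering, training,
    prediction, optional LOOCV; writes all artifacts plus a manifest.

    Returns the manifest dict.  Any stage failure is re-raised as
    :class:`PipelineError` with the stage name prefixed.
    """

    def stage(name, fn):
        try:
            logger.info("stage %s", name)
            return fn()
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(name, e) from e

    stage("validate", config.validate)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    Y0 = stage("read_interactions", lambda: read_interactions(config.interactions))

    def build_lnc_sim():
        if config.lnc_sim is not None:
            return read_similarity(config.lnc_sim)
        recs = read_fasta(config.lnc_fasta, NUCLEOTIDE)
        S = normalized_similarity_matrix(recs, config.nucleotide_scoring)
        write_similarity(S, out / "lncrna_similarity.tsv")
        return S

    def build_prot_sim():
        if config.prot_sim is not None:
            return read_similarity(config.prot_sim)
        recs = read_fasta(config.prot_fasta, PROTEIN)
        S = normalized_similarity_matrix(recs, config.protein_scoring)
        write_similarity(S, out / "protein_similarity.tsv")
        return S

    S_l = stage("lncrna_similarity", build_lnc_sim)
    S_p = stage("protein_similarity", build_prot_sim)

    def do_filter():
        Y = filter_entities(Y0, config.min_degree)
        write_interactions(Y, out / "interactions_filtered.tsv")
        return Y

    Y = stage("filter", do_filter)
    S_l = stage("align_lnc_sim", lambda: align_similarity(S_l, Y.lncrna_ids))
    S_p = stage("align_prot_sim", lambda: align_similarity(S_p, Y.protein_ids))

    def do_train():
        model = fit(Y, S_l, S_p, config.hyperparameters)
        save_model(model, out / "model.json")
        return model

    model = stage("train", do_train)

    def do_predict():
        scores = predict(model, Y)
        write_scores(scores, out / "scores.tsv")
        write_ranked_pairs(scores, out / "ranked_pairs.tsv", exclude=Y)
        return scores

    stage("predict", do_predict)

    report = None
    if config.run_loocv:
        def do_loocv():
            rep = loocv(
                Y, S_l, S_p, config.hyperparameters,
                fast=config.fast_loocv, threshold=config.threshold,
            )
            _write_report(rep, out)
            return rep

        report = stage("loocv", do_loocv)

    manifest = {
        "package": "lpinrlmf",
        "version": __version__,
        "seed": config.hyperparameters.seed,
        "config": {
            "interactions": str(config.interactions),
            "lnc_fasta": str(config.lnc_fasta) if config.lnc_fasta else None,
            "prot_fasta": str(config.prot_fasta) if config.prot_fasta else None,
            "lnc_sim": str(config.lnc_sim) if config.lnc_sim else None,
            "prot_sim": str(config.prot_sim) if config.prot_sim else None,
            "min_degree": config.min_degree,
            "hyperparameters": dataclasses.asdict(config.hyperparameters),
            "run_loocv": config.run_loocv,
            "fast_loocv": config.fast_loocv,
            "threshold": config.threshold,
        },
        "shape": {"lncrnas": len(Y.lncrna_ids), "proteins": len(Y.protein_ids),
                  "positives": Y.n_positives},
        "outputs": sorted(
            p.name
            for p in out.iterdir()
            if p.is_file()
            and p.name != "manifest.json"
            and not p.name.endswith(".partial")
        ),
    }
    if report is not None:
        manifest["loocv"] = {
            "AUC": report.auc, "AUPR": report.aupr,
            "threshold": report.threshold,
            "ACC": report.metrics.ACC, "SEN": report.metrics.SEN,
            "PRE": report.metrics.PRE, "F1": report.metrics.F1,
        }
    with atomic_write(out / "manifest.json") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
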