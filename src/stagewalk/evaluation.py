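"""Control-set benchmarks and ranking metrics.

The candidate set is the union of a test set (known disease genes present
in the ranking) and a control set built by one of three schemes:

ALI  Artificial Linked Interval — per test gene, the ``n_controls`` genes
     nearest on the same chromosome by midpoint distance (mimics linkage
     intervals around an implicated locus);
RC   Randomized Controls — ``n_controls`` uniform draws per test gene from
     the universe minus all test genes (mimics exome-study candidate lists);
WG   Whole Genome — every universe gene that is not a test gene.

Metrics are computed on the ranking restricted to the candidate set:
Topk_Precision = |Rk ∩ test| / k, Topk_Recall = |Rk ∩ test| / |test|,
plus AUROC (equivalent to the normalized Mann-Whitney U) and AUPRC (step
interpolation, i.e. average precision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import GeneAnnotation, GeneSet, ValidationError
from .propagation import RankedGeneList

logger = logging.getLogger(__name__)

SCHEMES = ("ALI", "RC", "WG")
DEFAULT_KS = (5, 10, 50, 100, 200)


@dataclass
class CandidateSet:
    """Disjoint test and control gene sets plus the scheme that built them."""

    test: frozenset[str]
    controls: frozenset[str]
    scheme: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.test = frozenset(self.test)
        self.controls = frozenset(self.controls)
        if not self.test or not self.controls:
            raise ValidationError("test and control sets must both be non-empty")
        if self.test & self.controls:
            raise ValidationError("test and control sets overlap")

    @property
    def candidates(self) -> frozenset[str]:
        return self.test | self.controls


@dataclass
class EvaluationReport:
    """Per-k precision/recall plus the two curve areas for one scheme."""

    scheme: str
    topk_precision: dict[int, float]
    topk_recall: dict[int, float]
    auroc: float
    auprc: float
    n_test: int
    n_controls: int
    meta: dict = field(default_factory=dict)

    def to_rows(self) -> list[tuple[str, object]]:
        rows: list[tuple[str, object]] = [
            ("scheme", self.scheme),
            ("n_test", self.n_test),
            ("n_controls", self.n_controls),
        ]
        for k in sorted(self.topk_precision):
            rows.append((f"top{k}_precision", repr(self.topk_precision[k])))
            rows.append((f"top{k}_recall", repr(self.topk_recall[k])))
        rows.append(("auroc", repr(self.auroc)))
        rows.append(("auprc", repr(self.auprc)))
        return rows


def build_control_set(
    test: GeneSet,
    scheme: str,
    universe: list[str],
    annotation: GeneAnnotation | None = None,
    n_controls: int = 99,
    seed: int | None = None,
) -> CandidateSet:
    """Build the candidate set for one evaluation scheme.

    ``universe`` is the ranked gene list (scored genes). Test genes absent
    from the universe are ignored; controls drawn for different test genes
    are pooled with duplicates removed, and a gene that is both test and
    would-be control stays test-only.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    uni = list(universe)
    uni_set = set(uni)
    test_in = frozenset(g for g in test.members if g in uni_set)
    if not test_in:
        raise ValidationError("no test genes present in the ranking universe")
    non_test = [g for g in uni if g not in test_in]

    if scheme == "WG":
        controls = set(non_test)
    elif scheme == "RC":
        rng = np.random.default_rng(seed)
        controls = set()
        pool = np.array(sorted(non_test))
        n_draw = min(n_controls, pool.size)
        for _ in sorted(test_in):
            controls.update(rng.choice(pool, size=n_draw, replace=False).tolist())
    else:  # ALI
        if annotation is None:
            raise ValidationError("ALI scheme requires gene coordinates")
        mid = annotation.midpoints()
        controls = set()
        for t in sorted(test_in):
            if t not in annotation:
                logger.warning("ALI: test gene %s has no coordinates; skipped", t)
                continue
            chrom = annotation.table.loc[t, "chrom"]
            same = [
                g
                for g in non_test
                if g in annotation and annotation.table.loc[g, "chrom"] == chrom
            ]
            if len(same) < n_controls:
                logger.warning(
                    "ALI: chromosome %s has only %d candidate controls for %s "
                    "(requested %d); taking all",
                    chrom,
                    len(same),
                    t,
                    n_controls,
                )
            # nearest by midpoint distance; ties broken by ascending symbol
            same.sort(key=lambda g: (abs(mid[g] - mid[t]), g))
            controls.update(same[:n_controls])
    if not controls:
        raise ValidationError(f"scheme {scheme} produced no control genes")
    return CandidateSet(test=test_in, controls=frozenset(controls), scheme=scheme, seed=seed)


def _restrict(ranking: RankedGeneList, cand: CandidateSet) -> tuple[list[str], np.ndarray]:
    keep = cand.candidates
    genes, scores = [], []
    for g, s in zip(ranking.genes, ranking.scores):
        if g in keep:
            genes.append(g)
            scores.append(s)
    if not genes:
        raise ValidationError("no candidate genes present in the ranking")
    return genes, np.asarray(scores)


def topk_metrics(
    ranking: RankedGeneList, cand: CandidateSet, ks=DEFAULT_KS
) -> tuple[dict[int, float], dict[int, float]]:
    """Top-k precision and recall on the candidate-restricted ranking."""
    genes, _ = _restrict(ranking, cand)
    n_test = len(cand.test & set(genes))
    if n_test == 0:
        raise ValidationError("no test genes in the restricted ranking")
    precision, recall = {}, {}
    for k in ks:
        kk = int(k)
        if kk <= 0:
            raise ValidationError(f"k must be positive, got {k}")
        if kk > len(genes):
            logger.warning("k=%d exceeds candidate list size %d; truncating", kk, len(genes))
            kk = len(genes)
        hits = sum(1 for g in genes[:kk] if g in cand.test)
        precision[int(k)] = hits / kk
        recall[int(k)] = hits / n_test
    return precision, recall


def curve_metrics(ranking: RankedGeneList, cand: CandidateSet) -> tuple[float, float]:
    """AUROC and AUPRC over the candidate-restricted ranking.

    Test genes are the positive class. Tied scores contribute their average
    rank to the ROC area (trapezoidal / Mann-Whitney convention); the PR
    area uses step interpolation (average precision).
    """
    genes, scores = _restrict(ranking, cand)
    labels = np.array([1 if g in cand.test else 0 for g in genes])
    if labels.min() == labels.max():
        raise ValidationError("candidate set restricted to the ranking has a single class")
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    return auroc, auprc


def evaluate_ranking(
    ranking: RankedGeneList,
    test: GeneSet,
    scheme: str = "WG",
    annotation: GeneAnnotation | None = None,
    n_controls: int = 99,
    seed: int | None = None,
    ks=DEFAULT_KS,
) -> EvaluationReport:
    """Build the control set and compute all four metrics in one call."""
    cand = build_control_set(
        test, scheme, list(ranking.genes), annotation=annotation, n_controls=n_controls, seed=seed
    )
    precision, recall = topk_metrics(ranking, cand, ks=ks)
    auroc, auprc = curve_metrics(ranking, cand)
    return EvaluationReport(
        scheme=scheme,
        topk_precision=precision,
        topk_recall=recall,
        auroc=auroc,
        auprc=auprc,
        n_test=len(cand.test),
        n_controls=len(cand.controls),
        meta={"n_controls_requested": n_controls, "seed": seed},
    )


def write_report(report: EvaluationReport, path) -> None:
    """Write an evaluation report as two-column TSV (metric, value)."""
    with open(path, "w") as fh:
        for key, value in report.to_rows():
            fh.write(f"{key}\t{value}\n")
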