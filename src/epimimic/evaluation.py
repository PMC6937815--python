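"""Peptide-epitope mimicry evaluation and chance baselines.

Sensitivity (Se) is the fraction of epitope residues represented in the
peptide; positive predictive value (PPV) is the fraction of peptide
residues corresponding to epitope residues. Both are computed in two
modes: *composition* (amino-acid identity only, multiset matching) and
*position-aware* (a peptide position counts only if its source residue in
the antigen is an epitope residue; linker positions are matched last, by
identity, against still-uncredited epitope residues).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import (
    DesignedPeptide,
    Epitope,
    EvaluationResult,
    LinkerPosition,
    MethodSummary,
    ProteinStructure,
)

__all__ = [
    "evaluate_composition",
    "evaluate_position_aware",
    "method_performance",
    "size_difference_analysis",
    "random_baseline",
    "chance_probability",
    "write_evaluation_tsv",
]

DEFAULT_THRESHOLD = 0.7


def evaluate_composition(
    peptide: DesignedPeptide, epitope: Epitope, antigen: ProteinStructure
) -> EvaluationResult:
    """Se/PPV by amino-acid identity only (multiset matching).

    tp = sum over amino acids of min(count in peptide, count in epitope);
    each epitope residue credits at most one peptide position.
    """
    pep_counts = Counter(peptide.sequence)
    epi_counts = Counter(antigen[k].aa for k in epitope.residues)
    tp = sum((pep_counts & epi_counts).values())
    result = EvaluationResult(
        tp=tp,
        fp=peptide.final_length - tp,
        fn=epitope.size - tp,
        mode="composition",
        valid=bool(peptide.sequence) and epitope.size > 0,
    )
    return result


def evaluate_position_aware(
    peptide: DesignedPeptide, epitope: Epitope, antigen: ProteinStructure
) -> EvaluationResult:
    """Se/PPV honouring residue positions.

    A non-linker peptide position is a true positive iff its source
    residue key is an epitope residue (each epitope residue creditable
    once). Linker positions are compared only after all the other
    positions, by amino-acid identity against the still-uncredited epitope
    residues.
    """
    remaining = set(epitope.residues)
    tp = 0
    linker_letters: list[str] = []
    for aa, prov in zip(peptide.sequence, peptide.positions):
        if isinstance(prov, LinkerPosition):
            linker_letters.append(aa)
        elif prov in remaining:
            remaining.discard(prov)
            tp += 1
    linker_counts = Counter(linker_letters)
    remaining_counts = Counter(antigen[k].aa for k in remaining)
    tp += sum((linker_counts & remaining_counts).values())
    return EvaluationResult(
        tp=tp,
        fp=peptide.final_length - tp,
        fn=epitope.size - tp,
        mode="position_aware",
        valid=bool(peptide.sequence) and epitope.size > 0,
    )


def method_performance(
    results_by_antigen: Mapping[str, Sequence[EvaluationResult]],
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "",
) -> MethodSummary:
    """Aggregate one method's results over a benchmark.

    ``prop_above`` counts peptides with Se AND PPV strictly above the
    threshold; ``n_antigens_hit`` counts antigens with at least one such
    peptide.
    """
    all_results = [r for rs in results_by_antigen.values() for r in rs]
    if not all_results:
        raise ValueError("empty result set")

    def qualifies(r: EvaluationResult) -> bool:
        return r.se > threshold and r.ppv > threshold

    n = len(all_results)
    return MethodSummary(
        method=method,
        n_peptides=n,
        mean_se=float(np.mean([r.se for r in all_results])),
        mean_ppv=float(np.mean([r.ppv for r in all_results])),
        prop_above=sum(1 for r in all_results if qualifies(r)) / n,
        n_antigens_hit=sum(
            1 for rs in results_by_antigen.values() if any(qualifies(r) for r in rs)
        ),
        threshold=threshold,
    )


def size_difference_analysis(
    records: Sequence[tuple[DesignedPeptide, Epitope, EvaluationResult]],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Qualifying-peptide counts binned by |peptide length - epitope size|.

    Returns a DataFrame indexed by the absolute size difference with the
    number of peptides and the number passing the Se/PPV threshold in each
    bin.
    """
    rows: dict[int, list[int]] = {}
    for pep, epi, res in records:
        delta = abs(pep.final_length - epi.size)
        counts = rows.setdefault(delta, [0, 0])
        counts[0] += 1
        if res.se > threshold and res.ppv > threshold:
            counts[1] += 1
    df = pd.DataFrame(
        [
            {"size_difference": d, "n_peptides": c[0], "n_qualifying": c[1]}
            for d, c in sorted(rows.items())
        ]
    ).set_index("size_difference")
    return df


def random_baseline(
    antigen: ProteinStructure,
    n_peptides: int,
    lengths: Sequence[int],
    rng_seed: int,
) -> list[DesignedPeptide]:
    """Random peptides matching the antigen's amino-acid composition.

    Each position is an i.i.d. draw from the antigen's residue-frequency
    distribution; peptide lengths are drawn from the supplied empirical
    length distribution. Fully reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    letters = [r.aa for r in antigen.residues()]
    if not letters:
        raise ValueError("antigen has no residues")
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty length distribution")
    peptides = []
    for i in range(n_peptides):
        length = int(rng.choice(lengths))
        seq = "".join(rng.choice(letters) for _ in range(length))
        peptides.append(
            DesignedPeptide(
                sequence=seq,
                positions=[LinkerPosition("RND")] * length,
                segments_used=[],
                method="random",
                requested_length=None,
                reference=f"random{i}",
            )
        )
    return peptides


def chance_probability(
    peptide_sequence: str, antigen: ProteinStructure, accessible_only: bool = True
) -> float:
    """Probability of drawing a given peptide sequence by chance.

    Positions are drawn without replacement from the antigen's
    (accessible) residues. With n_X / p_X the occurrences of amino acid X
    in the protein and the peptide, the probability is
    ``prod_X A(n_X, p_X) / A(n, P)`` with ``A(n, p) = n!/(n-p)!``,
    evaluated in log space. Zero when some p_X exceeds n_X.
    """
    residues = (
        antigen.accessible_residues() if accessible_only else list(antigen.residues())
    )
    counts = Counter(r.aa for r in residues)
    pep = Counter(peptide_sequence)
    n, p = sum(counts.values()), sum(pep.values())
    if p > n:
        raise ValueError("peptide longer than the available residue pool")
    if any(pep[aa] > counts.get(aa, 0) for aa in pep):
        return 0.0

    def log_arr(n_, p_):
        return gammaln(n_ + 1) - gammaln(n_ - p_ + 1)

    log_p = sum(log_arr(counts[aa], pep[aa]) for aa in pep) - log_arr(n, p)
    return float(np.exp(log_p))


def write_evaluation_tsv(
    records: Sequence[tuple[DesignedPeptide, str, EvaluationResult]], path
) -> None:
    """Write evaluation results as TSV: peptide, method, antigen, mode,
    counts and metrics."""
    rows = [
        {
            "peptide": str(p.reference),
            "method": p.method,
            "antigen": antigen_id,
            "mode": r.mode,
            "tp": r.tp,
            "fp": r.fp,
            "fn": r.fn,
            "se": r.se,
            "ppv": r.ppv,
        }
        for p, antigen_id, r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
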