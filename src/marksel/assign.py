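"""Exclusion-based paternity assignment and truth scoring.

Because the mother is homozygous for the reference allele everywhere, an
offspring's dosage *is* its paternal gamete. A candidate father is excluded
at a locus when that gamete is Mendelian-impossible for him: gamete 1 against
a father of dosage 0, or gamete 0 against dosage 2 (the opposing-homozygote
logic of classical exclusion). Missing calls on either side are skipped.
Candidates with at most ``max_mismatch`` incompatible loci are retained; a
unique survivor is assigned, anything else — zero survivors or a tie — is
left unassigned rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discrimination import MarkerSolution
from .panel import GenotypePanel
from .simulate import OffspringSet

__all__ = [
    "AssignmentResult",
    "count_mismatches",
    "assign_paternity",
    "score_assignments",
]


def count_mismatches(offspring: np.ndarray, father: np.ndarray) -> int:
    """Number of loci where the offspring's paternal gamete excludes the father."""
    o = np.asarray(offspring, dtype=float)
    f = np.asarray(father, dtype=float)
    if o.shape != f.shape:
        raise ValueError("vectors cover different marker sets")
    return int(((o == 1.0) & (f == 0.0)).sum() + ((o == 0.0) & (f == 2.0)).sum())


@dataclass
class AssignmentResult:
    """Per-offspring assignments with mismatch counts, margins, and labels."""

    table: pd.DataFrame  # offspring, assigned, n_retained, best_mismatches, margin, label

    @property
    def n_offspring(self) -> int:
        return len(self.table)

    def counts(self) -> dict[str, int]:
        c = self.table["label"].value_counts().to_dict()
        return {
            "TP": int(c.get("true positive", 0)),
            "FP": int(c.get("false positive", 0)),
            "unassigned": int(c.get("unassigned", 0)),
        }


def assign_paternity(
    offspring: OffspringSet,
    panel: GenotypePanel,
    solution: MarkerSolution,
    max_mismatch: int = 0,
) -> AssignmentResult:
    """Assign each offspring to the unique non-excluded candidate father.

    Both genotype sets are restricted to the solution's markers. Labels
    ("true positive" / "false positive" / "unassigned") are computed against
    the offspring set's recorded true fathers.
    """
    if panel.n_individuals == 0:
        raise ValueError("empty candidate-father set")
    if not solution.selected:
        raise ValueError("empty marker solution")
    pk = panel.marker_indices(solution.selected)
    off_lookup = {mk: k for k, mk in enumerate(offspring.marker_ids)}
    try:
        ok = np.array([off_lookup[mk] for mk in solution.selected], dtype=int)
    except KeyError as exc:
        raise KeyError(f"offspring not typed at marker {exc.args[0]!r}") from None

    O = offspring.dosages[:, ok]
    F = panel.dosages[:, pk]
    # mismatch[o, c] = #(gamete 1 vs father 0) + #(gamete 0 vs father 2)
    mism = (O == 1.0).astype(float) @ (F == 0.0).T.astype(float)
    mism += (O == 0.0).astype(float) @ (F == 2.0).T.astype(float)
    mism = mism.astype(int)

    retained = mism <= max_mismatch
    records = []
    for o in range(offspring.n_offspring):
        surv = np.flatnonzero(retained[o])
        order = np.argsort(mism[o], kind="stable")
        best, second = int(mism[o, order[0]]), (
            int(mism[o, order[1]]) if len(order) > 1 else None
        )
        margin = None if second is None else second - best
        if surv.size == 1:
            assigned = panel.individual_ids[surv[0]]
        else:
            assigned = None
        truth = offspring.true_father[o]
        if assigned is None:
            label = "unassigned"
        elif assigned == truth:
            label = "true positive"
        else:
            label = "false positive"
        records.append(
            {
                "offspring": offspring.offspring_ids[o],
                "assigned": assigned,
                "n_retained": int(surv.size),
                "best_mismatches": best,
                "margin": margin,
                "true_father": truth,
                "label": label,
            }
        )
    return AssignmentResult(table=pd.DataFrame.from_records(records))


def score_assignments(
    result: AssignmentResult, truth: dict[str, str] | None = None
) -> dict[str, float]:
    """Summary counts and rates; TP + FP + unassigned partitions the offspring.

    ``truth`` optionally re-labels against an external offspring -> father
    mapping (it must cover every offspring); by default the labels already on
    the result are tallied.
    """
    table = result.table
    if truth is not None:
        missing = set(table["offspring"]) - set(truth)
        if missing:
            raise KeyError(f"truth missing offspring ids: {sorted(missing)[:5]}")
        assigned = table["assigned"]
        expected = table["offspring"].map(truth)
        label = np.where(
            assigned.isna(),
            "unassigned",
            np.where(assigned == expected, "true positive", "false positive"),
        )
        table = table.assign(label=label)
        result = AssignmentResult(table=table)
    counts = result.counts()
    total = result.n_offspring
    assert counts["TP"] + counts["FP"] + counts["unassigned"] == total
    return {
        **counts,
        "total": total,
        "tp_rate": counts["TP"] / total if total else 0.0,
        "fp_rate": counts["FP"] / total if total else 0.0,
        "unassigned_rate": counts["unassigned"] / total if total else 0.0,
    }
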