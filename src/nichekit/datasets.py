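"""Bundled reference data.

The package ships the published interspecific pairwise niche-comparison
score matrix for the martin genus *Progne* (nine species, lower
triangle of -2..+2 scores; blank cells are comparisons consistent with
random variation and load as 0). It serves as a small real-world test
object for the score-matrix bookkeeping.
"""

from __future__ import annotations

import csv
from importlib import resources
from itertools import combinations

from .overlap import ScoreMatrix

_SCORES_FILE = "progne_pairwise_scores.csv"


def load_progne_scores() -> ScoreMatrix:
    """Published pairwise niche-comparison scores within *Progne*."""
    path = resources.files("nichekit.data") / _SCORES_FILE
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        taxa = header[1:]
        matrix = ScoreMatrix(list(taxa))
        for row in reader:
            row_taxon = row[0]
            for col_taxon, cell in zip(taxa, row[1:]):
                if row_taxon == col_taxon:
                    continue
                if cell.strip():
                    matrix.scores[frozenset((row_taxon, col_taxon))] = int(cell)
    # untested / random-variation cells score 0
    for a, b in combinations(taxa, 2):
        matrix.scores.setdefault(frozenset((a, b)), 0)
    return matrix
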