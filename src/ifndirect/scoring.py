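"""Per-cell gene-set scores: the ISG Score and the Direct (DNA-sensing) Score.

A score is the sum of a cell's **raw** UMI counts over a fixed gene panel,
divided by the cell's total counts and scaled by 10^4:

    score_c = 1e4 * sum_{g in panel} x_gc / sum_{g} x_gc

Raw counts are used deliberately — never integrated/batch-corrected values —
so scores are independent of the integration stage and bounded in [0, 1e4].

The ISG panel is the 18-gene interferon-stimulated-gene list used to quantify
the type I IFN response; the Direct panel (Ccl5, Cdk8, Cxcl2, Cd74) is the
4-gene signature of cells that sense cytosolic dsDNA cell-autonomously, i.e.
independent of IFNAR-mediated paracrine amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetPanel",
    "ISG_PANEL",
    "DIRECT_PANEL",
    "PHASE_PANELS",
    "SUBSET_MARKERS",
    "SYMBOL_ALIASES",
    "resolve_panel",
    "gene_set_score",
    "isg_score",
    "direct_score",
    "threshold_isg_positive",
]


@dataclass(frozen=True)
class GeneSetPanel:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"panel '{self.name}' is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel '{self.name}' has duplicate symbols")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)


#: 18 interferon-stimulated genes used for the per-cell ISG Score.  The
#: symbols "Gpb5"/"Gpb2" are kept verbatim from the source table; they are
#: almost certainly the guanylate-binding proteins Gbp5/Gbp2, so an alias map
#: is applied at match time (see :data:`SYMBOL_ALIASES`).
ISG_PANEL = GeneSetPanel("ISG", (
    "Ifi204", "Isg15", "Irf7", "Ifit1", "Rsad2", "Oasl2", "Oas3", "Gpb5",
    "Bst2", "Ifit2", "Ifit3", "Oas2", "Isg20", "Cxcl10", "Oasl1", "Gpb2",
    "Ccl5", "Ccl3",
))

#: The 4-gene direct DNA-sensing signature.
DIRECT_PANEL = GeneSetPanel("Direct", ("Ccl5", "Cdk8", "Cxcl2", "Cd74"))

#: Cell-cycle phase marker pairs.  The G1 label for Top2a/Cenpa follows the
#: source study's own nomenclature (conventionally these are G2/M markers);
#: the mapping is configuration, not hard-coded downstream.
PHASE_PANELS = {
    "S": GeneSetPanel("S", ("Mcm5", "Mcm6")),
    "G1": GeneSetPanel("G1", ("Top2a", "Cenpa")),
    "G2": GeneSetPanel("G2", ("Birc5", "Nusap1")),
}

#: Canonical markers of the macrophage subsets modeled by the simulator.
SUBSET_MARKERS = {
    "Fabp4": GeneSetPanel("Fabp4", ("Fabp4", "Fabp5")),
    "MHCII": GeneSetPanel("MHCII", ("H2-Aa", "H2-Ab1")),
    "Progenitor": GeneSetPanel("Progenitor", ("S100a4", "S100a6")),
    "Macrophage": GeneSetPanel("Macrophage", ("Ms4a7",)),
}

#: Printed-symbol -> murine-convention aliases tried when a panel symbol is
#: absent from a matrix.
SYMBOL_ALIASES = {"Gpb5": "Gbp5", "Gpb2": "Gbp2"}


def resolve_panel(panel: GeneSetPanel, gene_names) -> tuple[list[int], list[str]]:
    """Map panel symbols to row indices, applying aliases for missing symbols.

    Returns ``(row_indices, missing_symbols)``.  Alias substitutions are
    logged so silent symbol drift is visible.
    """
    index = {g: i for i, g in enumerate(gene_names)}
    rows, missing = [], []
    for sym in panel:
        if sym in index:
            rows.append(index[sym])
        elif SYMBOL_ALIASES.get(sym) in index:
            rows.append(index[SYMBOL_ALIASES[sym]])
            logger.info("panel %s: symbol %s matched via alias %s",
                        panel.name, sym, SYMBOL_ALIASES[sym])
        else:
            missing.append(sym)
    return rows, missing


def gene_set_score(cm: CountMatrix, panel: GeneSetPanel,
                   scale: float = 10_000.0) -> np.ndarray:
    """Per-cell panel score on raw counts, in [0, ``scale``].

    Missing panel genes contribute zero counts (with a warning) so public
    panels still work on gene-filtered matrices; a panel with *no* gene
    present is an error.
    """
    rows, missing = resolve_panel(panel, cm.gene_names)
    if not rows:
        raise ValueError(
            f"no gene of panel '{panel.name}' present in the matrix")
    if missing:
        logger.warning("panel %s: %d symbol(s) absent, treated as zero: %s",
                       panel.name, len(missing), missing)
    totals = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero-total cell(s), cannot score: "
            f"{[cm.barcodes[i] for i in zero[:5]]}")
    panel_counts = np.asarray(cm.counts[rows, :].sum(axis=0)).ravel()
    return scale * panel_counts / totals


def isg_score(cm: CountMatrix) -> np.ndarray:
    """ISG Score: summed raw reads of the 18 shipped ISGs per 10^4 reads."""
    return gene_set_score(cm, ISG_PANEL)


def direct_score(cm: CountMatrix) -> np.ndarray:
    """Direct Score: summed raw reads of Ccl5/Cdk8/Cxcl2/Cd74 per 10^4 reads."""
    return gene_set_score(cm, DIRECT_PANEL)


def threshold_isg_positive(scores, method: str = "otsu"):
    """Cluster-free binary ISG+ call on per-cell scores.

    Otsu's criterion (minimum intra-class variance) is applied to
    ``log1p(score)``, which separates the near-zero bulk from the induced
    tail.  Returns ``(calls, threshold)`` where ``threshold`` is on the
    original score scale.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 20:
        raise ValueError("need at least 20 cells to estimate a threshold")
    if method != "otsu":
        raise ValueError(f"unknown thresholding method '{method}'")
    if np.allclose(scores, scores[0]):
        import warnings
        warnings.warn("constant scores: all cells called ISG-negative")
        return np.zeros(scores.size, dtype=bool), float("inf")
    from skimage.filters import threshold_otsu

    t_log = threshold_otsu(np.log1p(scores))
    threshold = float(np.expm1(t_log))
    return scores > threshold, threshold
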