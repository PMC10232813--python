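"""Synthetic scRNA-seq generator with planted macrophage population structure.

The generator emulates cultured bone-marrow-derived macrophages (BMDMs)
profiled under up to four arms: vehicle control, immune-stimulatory dsDNA,
dsDNA + IFNAR-neutralizing antibody (secondary amplification blocked), and a
leaky IFNAR-knockout arm.  It plants exactly the structure the downstream
analysis is designed to recover, with full ground-truth labels:

* six BMDM subsets — two proliferating (``ReplG2G1``, ``ReplSG1``), three
  non-proliferating strata defined by Fabp4 and MHC class II
  (``Fabp4negMHCIIneg``, ``Fabp4posMHCIIneg``, ``Fabp4posMHCIIpos``) and an
  S100a4/S100a6+ ``Progenitor``;
* uniform ISG induction across all subsets under dsDNA;
* a rare, Ccl5-high, ISG+ *direct responder* population inside the
  Fabp4+MHCII- subset present in both dsDNA-exposed arms (direct sensing
  precedes amplification), the only ISG+ cells under IFNAR blockade;
* optional condition-3 substructure so the blocked arm carries eight
  separable groups (two non-proliferating subsets each split in two
  sub-states, one of which is the ISG+ direct group itself);
* deliberate QC-failure cells (high mitochondrial content or out-of-range
  library size) at a configurable rate.

Counts are negative binomial with var = mu + theta * mu^2 (gamma-Poisson
mixture); per-cell library sizes are log-normal.  ``expected_mean`` exposes
the exact per-gene NB mean used for sampling and is the analytic oracle the
test-suite checks the sampler against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CONDITIONS, CountMatrix, Dataset
from .scoring import (DIRECT_PANEL, ISG_PANEL, PHASE_PANELS, SUBSET_MARKERS,
                      SYMBOL_ALIASES)

__all__ = [
    "SUBSETS",
    "GeneratorConfig",
    "CellState",
    "GeneModel",
    "expected_mean",
    "generate_dataset",
    "generate_datasets",
]

SUBSETS = ("ReplG2G1", "ReplSG1", "Fabp4negMHCIIneg", "Fabp4posMHCIIneg",
           "Fabp4posMHCIIpos", "Progenitor")

_DEFAULT_PROPORTIONS = {
    "ReplG2G1": 0.15,
    "ReplSG1": 0.15,
    "Fabp4negMHCIIneg": 0.20,
    "Fabp4posMHCIIneg": 0.25,
    "Fabp4posMHCIIpos": 0.15,
    "Progenitor": 0.10,
}

#: emitted gene symbols for the ISG panel (murine-convention spellings).
_ISG_EMITTED = tuple(SYMBOL_ALIASES.get(g, g) for g in ISG_PANEL)

# phases sampled within each proliferating subset (major phase first)
_SUBSET_PHASES = {"ReplSG1": ("S", "G1"), "ReplG2G1": ("G2", "G1")}


@dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults define the simulated study.

    The headline effect sizes (``isg_fold_secondary``, ``isg_fold_direct``,
    ``ccl5_extra_fold``, ``direct_fraction``, ``marker_fold``) are calibration
    assumptions — the study they emulate reports no magnitudes — and are
    deliberately configuration, not constants.
    """

    n_cells_per_condition: int = 3000
    n_genes: int = 5000
    subset_proportions: dict = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    nb_dispersion: float = 0.3
    libsize_log_mean: float = math.log(4000.0)
    libsize_log_sd: float = 0.35
    isg_fold_secondary: float = 8.0
    isg_fold_direct: float = 8.0
    direct_fraction: float = 0.03
    ccl5_extra_fold: float = 6.0
    marker_fold: float = 6.0
    mito_fraction_mean: float = 0.004
    mito_fraction_sd: float = 0.002
    qc_outlier_fraction: float = 0.05
    condition3_substructure: bool = True
    seed: int = 0
    # -- structural knobs not tied to a single published quantity ---------
    n_mito_genes: int = 50
    n_program_genes: int = 30       # private expression program per subset
    n_substate_genes: int = 30      # program of the extra condition-3 sub-state
    substate_fold: float = 6.0
    n_isg_program_genes: int = 120  # extended IFN-response program (beyond
                                    # the scored panel; IFN induces hundreds
                                    # of effector genes)
    program_gene_weight: float = 1.5     # baseline weight of response/state
                                         # program genes (low: mostly off)
    panel_baseline_weight: float = 4.0   # baseline abundance of named genes
    ms4a7_weight: float = 8.0            # pan-macrophage marker, always high
    baseline_log_sigma: float = 1.7      # lognormal sigma of background genes
    phase_major_fraction: float = 0.6    # majority phase within Repl subsets
    leaky_ko_fraction: float = 0.05      # scattered ISG+ cells in the KO arm

    def __post_init__(self):
        s = sum(self.subset_proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"subset_proportions sum to {s}, expected 1")
        if set(self.subset_proportions) != set(SUBSETS):
            raise ValueError(f"subset_proportions keys must be {SUBSETS}")
        for name in ("direct_fraction", "qc_outlier_fraction",
                     "leaky_ko_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("isg_fold_secondary", "isg_fold_direct",
                     "ccl5_extra_fold", "marker_fold", "substate_fold"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        needed = (len(self._named_genes()) + self.n_mito_genes
                  + 7 * self.n_program_genes + self.n_substate_genes
                  + self.n_isg_program_genes)
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small; need >= {needed} to hold "
                "all panel, mitochondrial and program genes")

    @staticmethod
    def _named_genes() -> list[str]:
        named: list[str] = []
        for g in (*_ISG_EMITTED, *DIRECT_PANEL,
                  *(g for p in PHASE_PANELS.values() for g in p),
                  *(g for p in SUBSET_MARKERS.values() for g in p)):
            if g not in named:
                named.append(g)
        return named


@dataclass
class CellState:
    """Everything that determines one cell's NB mean vector."""

    subset: str
    condition: str
    phase: Optional[str] = None
    substate: Optional[str] = None
    is_direct: bool = False
    leaky: bool = False
    libsize: float = 4000.0
    mito_fraction: float = 0.004


class GeneModel:
    """Deterministic gene universe + baseline abundances for a config.

    Built from ``config.seed`` only, independent of which conditions are
    sampled, so the same config always yields the same gene space.
    """

    def __init__(self, config: GeneratorConfig):
        self.config = config
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % (2**31), 7919]))
        named = config._named_genes()
        self.mito_genes = [f"mt-g{i + 1:02d}" for i in range(config.n_mito_genes)]
        n_filler = config.n_genes - len(named) - config.n_mito_genes
        filler = [f"g{i + 1:04d}" for i in range(n_filler)]
        self.gene_names: list[str] = named + self.mito_genes + filler
        self.index = {g: i for i, g in enumerate(self.gene_names)}

        # baseline relative abundances
        w = rng.lognormal(mean=0.0, sigma=config.baseline_log_sigma,
                          size=config.n_genes)
        for g in named:
            w[self.index[g]] = config.panel_baseline_weight
        w[self.index["Ms4a7"]] = config.ms4a7_weight
        self.weights = w

        self.is_mito = np.zeros(config.n_genes, dtype=bool)
        for g in self.mito_genes:
            self.is_mito[self.index[g]] = True

        # private expression programs: one block per subset (incl. both
        # proliferating subsets) plus one extra proliferation-shared block is
        # not needed — phase panels carry the shared cycling signal.
        pool = iter(filler)
        self.programs: dict[str, list[str]] = {}
        for subset in SUBSETS:
            self.programs[subset] = [next(pool) for _ in
                                     range(config.n_program_genes)]
        self.substate_program = [next(pool) for _ in
                                 range(config.n_substate_genes)]
        # a spare block keeps gene budget honest for future sub-states
        self.spare_program = [next(pool) for _ in range(config.n_program_genes)]
        # extended interferon-response program: induced together with the
        # scored panel, emulating the breadth of the ISGF3/IRF3 regulon
        self.isg_program = [next(pool) for _ in
                            range(config.n_isg_program_genes)]
        for g in self.isg_program + self.substate_program:
            w[self.index[g]] = config.program_gene_weight
        self.weights = w

        panel_rows = [self.index[g] for g in _ISG_EMITTED]
        program_rows = [self.index[g] for g in self.isg_program]
        self.isg_rows = np.array(panel_rows)
        self.isg_response_rows = np.array(panel_rows + program_rows)
        self.ccl5_row = self.index["Ccl5"]

    # ------------------------------------------------------------------
    def fold_vector(self, state: CellState) -> np.ndarray:
        """Multiplicative fold over baseline for every non-mito gene."""
        cfg = self.config
        fold = np.ones(cfg.n_genes)

        def bump(genes, f):
            for g in genes:
                fold[self.index[g]] *= f

        # subset identity
        bump(self.programs[state.subset], cfg.marker_fold)
        if state.subset in ("Fabp4posMHCIIneg", "Fabp4posMHCIIpos"):
            bump(SUBSET_MARKERS["Fabp4"], cfg.marker_fold)
        if state.subset == "Fabp4posMHCIIpos":
            bump(SUBSET_MARKERS["MHCII"], cfg.marker_fold)
            bump(["Cd74"], cfg.marker_fold)  # MHCII invariant chain
        if state.subset == "Progenitor":
            bump(SUBSET_MARKERS["Progenitor"], cfg.marker_fold)
        # cell cycle
        if state.phase is not None:
            bump(PHASE_PANELS[state.phase], cfg.marker_fold)
        # condition-3 sub-state program
        if state.substate == "B":
            bump(self.substate_program, cfg.substate_fold)
        # condition response (scored panel + extended IFN program)
        if state.condition == "dsDNA":
            fold[self.isg_response_rows] *= cfg.isg_fold_secondary
        elif state.condition == "dsDNA_IFNARAb" and state.is_direct:
            fold[self.isg_response_rows] *= cfg.isg_fold_direct
        elif state.condition == "dsDNA_IFNARKO" and state.leaky:
            fold[self.isg_response_rows] *= cfg.isg_fold_secondary
        if state.is_direct and state.condition in ("dsDNA", "dsDNA_IFNARAb"):
            fold[self.ccl5_row] *= cfg.ccl5_extra_fold
        return fold

    def rate_vectors(self, state: CellState) -> tuple[np.ndarray, np.ndarray]:
        """Normalized relative rates: (non-mito rates, mito rates).

        Non-mito rates sum to 1 over non-mito genes (zero on mito rows) and
        vice versa; the cell's mito fraction interpolates between them.
        """
        r = self.weights * self.fold_vector(state)
        non_mito = np.where(self.is_mito, 0.0, r)
        mito = np.where(self.is_mito, self.weights, 0.0)
        return non_mito / non_mito.sum(), mito / mito.sum()

    def mean_vector(self, state: CellState) -> np.ndarray:
        p_expr, p_mito = self.rate_vectors(state)
        return state.libsize * ((1.0 - state.mito_fraction) * p_expr
                                + state.mito_fraction * p_mito)


def expected_mean(config: GeneratorConfig, gene: str,
                  cell_state: CellState) -> float:
    """Exact NB mean for one gene in one cell state (the sampling oracle)."""
    model = GeneModel(config)
    if gene not in model.index:
        raise KeyError(f"unknown gene '{gene}'")
    return float(model.mean_vector(cell_state)[model.index[gene]])


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _draw_states(config: GeneratorConfig, condition: str,
                 rng: np.random.Generator
                 ) -> tuple[list[CellState], np.ndarray]:
    n = config.n_cells_per_condition
    subsets = rng.choice(list(SUBSETS),
                         p=[config.subset_proportions[s] for s in SUBSETS],
                         size=n)
    states: list[CellState] = []
    for subset in subsets:
        phase = None
        if subset in _SUBSET_PHASES:
            major, minor = _SUBSET_PHASES[subset]
            phase = major if rng.random() < config.phase_major_fraction else minor
        is_direct = bool(
            subset == "Fabp4posMHCIIneg"
            and condition in ("dsDNA", "dsDNA_IFNARAb")
            and rng.random() < config.direct_fraction)
        substate = None
        if (config.condition3_substructure and condition == "dsDNA_IFNARAb"
                and subset == "Fabp4negMHCIIneg"):
            substate = "B" if rng.random() < 0.5 else "A"
        leaky = bool(condition == "dsDNA_IFNARKO"
                     and rng.random() < config.leaky_ko_fraction)
        libsize = float(rng.lognormal(config.libsize_log_mean,
                                      config.libsize_log_sd))
        mito = float(np.clip(rng.normal(config.mito_fraction_mean,
                                        config.mito_fraction_sd),
                             0.0, 0.008))
        states.append(CellState(subset=subset, condition=condition,
                                phase=phase, substate=substate,
                                is_direct=is_direct, leaky=leaky,
                                libsize=libsize, mito_fraction=mito))
    # deliberate QC failures, overriding library size / mito content
    outlier = rng.random(n) < config.qc_outlier_fraction
    kinds = rng.random(n)
    for i in np.flatnonzero(outlier):
        st = states[i]
        kind = kinds[i]
        if kind < 0.3 and config.n_genes >= 2500:
            st.libsize = float(rng.lognormal(math.log(50_000.0), 0.2))
        elif kind < 0.6:
            st.libsize = float(rng.lognormal(math.log(80.0), 0.2))
        else:
            st.mito_fraction = float(rng.uniform(0.03, 0.12))
    return states, outlier


def _sample_counts(model: GeneModel, states: list[CellState],
                   rng: np.random.Generator) -> np.ndarray:
    """NB counts for all cells, grouped by identical fold profile."""
    cfg = model.config
    n_genes, n_cells = cfg.n_genes, len(states)
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    keys = [(s.subset, s.condition, s.phase, s.substate, s.is_direct, s.leaky)
            for s in states]
    shape = 1.0 / cfg.nb_dispersion
    for key in sorted(set(keys), key=repr):
        idx = np.array([i for i, k in enumerate(keys) if k == key])
        p_expr, p_mito = model.rate_vectors(states[idx[0]])
        lib = np.array([states[i].libsize for i in idx])
        mito = np.array([states[i].mito_fraction for i in idx])
        mu = (p_expr[:, None] * ((1.0 - mito) * lib)[None, :]
              + p_mito[:, None] * (mito * lib)[None, :])
        lam = rng.gamma(shape, cfg.nb_dispersion * mu)
        counts[:, idx] = rng.poisson(lam)
    return counts


def _cell_table(counts: np.ndarray, model: GeneModel,
                states: list[CellState], outlier: np.ndarray,
                condition: str) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    detected = (counts > 0).sum(axis=0)
    mito_counts = counts[model.is_mito, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)
    return pd.DataFrame({
        "barcode": [f"{condition}-{i:05d}" for i in range(len(states))],
        "condition": condition,
        "n_genes_detected": detected.astype(int),
        "total_counts": totals.astype(int),
        "pct_mito": pct_mito,
        "truth_subset": [s.subset for s in states],
        "truth_substate": [s.substate if s.substate is not None else ""
                           for s in states],
        "truth_phase": [s.phase if s.phase is not None else ""
                        for s in states],
        "truth_direct": [bool(s.is_direct) for s in states],
        "truth_leaky": [bool(s.leaky) for s in states],
        "truth_qc_outlier": outlier.astype(bool),
        "truth_libsize": [s.libsize for s in states],
        "truth_mito_fraction": [s.mito_fraction for s in states],
    })


def generate_datasets(config: GeneratorConfig,
                      conditions) -> dict[str, Dataset]:
    """One :class:`Dataset` per requested condition, fully deterministic."""
    conditions = list(conditions)
    if not conditions:
        raise ValueError("conditions list is empty")
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition '{c}'; valid: {CONDITIONS}")
    model = GeneModel(config)
    out: dict[str, Dataset] = {}
    for cond in conditions:
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(config.seed) % (2**31), CONDITIONS.index(cond)]))
        states, outlier = _draw_states(config, cond, rng)
        counts = _sample_counts(model, states, rng)
        cells = _cell_table(counts, model, states, outlier, cond)
        cm = CountMatrix(sp.csr_matrix(counts), model.gene_names,
                         cells["barcode"].tolist())
        out[cond] = Dataset(cm, cells)
    return out


def generate_dataset(config: GeneratorConfig,
                     conditions) -> tuple[CountMatrix, pd.DataFrame]:
    """All requested conditions concatenated into one matrix + cell table."""
    per_cond = generate_datasets(config, conditions)
    mats = [per_cond[c].counts.counts for c in conditions]
    cm = CountMatrix(
        sp.hstack(mats, format="csr"),
        per_cond[conditions[0]].counts.gene_names,
        [b for c in conditions for b in per_cond[c].counts.barcodes],
    )
    cells = pd.concat([per_cond[c].cells for c in conditions],
                      ignore_index=True)
    return cm, cells
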