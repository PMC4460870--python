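"""Synthetic inputs with known structure for every pipeline stage.

Three generators cover the three kinds of input the analysis consumes:

* **toy metabolic models** whose supply optima are hand-computable.  The
  canonical fixture ``TOY1`` has two amino acids A (yield 2 per substrate)
  and B (yield 1), a biomass consuming 1 A + 1 B, and substrate uptake 10 —
  its maximal growth rate is 20/3 and the supplies of an all-A / all-B /
  half-half protein at basal level 0.3 are 14, 7 and 28/3.
* **synthetic proteomes**: fixed-length random sequences over the toy
  alphabet with a bias knob pushing composition toward the cheapest
  (highest-yield) residue, mimicking the enrichment of highly expressed
  proteins in cheap residues.
* **expression and starvation tables** with planted rank correlations.  A
  Gaussian copula couples supply to translation efficiency (and to ribosome
  density and mRNA level) so that the *population Spearman correlation
  equals the target exactly*; replicate RPKMs carry lognormal noise of a
  chosen coefficient of variation.  Starvation fold changes have median
  ``1 + delta * (1 - supply percentile)``: ``delta`` is the planted
  buffering effect, zero means fold change independent of supply.

Every generator is a pure function of its inputs and a mandatory seed.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import Metabolite, Reaction, StoichiometricModel
from .seq_features import ProteinRecord
from .supply_fba import AminoAcidMap

__all__ = [
    "ToyModelSpec",
    "PlantedParams",
    "toy1_spec",
    "build_toy_model",
    "toy_aa_map",
    "random_toy_spec",
    "gen_proteome",
    "gen_expression",
    "gen_starvation",
    "expression_records",
    "DEFAULT_PROTEIN_LENGTH",
]

DEFAULT_PROTEIN_LENGTH = 300
_RXN_UB = 1000.0


@dataclass(frozen=True)
class ToyModelSpec:
    """Blueprint of a toy network: substrate -> amino acids -> biomass.

    ``yields[aa]`` is the amount of amino acid produced per unit substrate;
    ``biomass_composition[aa]`` the amount consumed per unit biomass flux.
    ``extra_biomass_components`` adds non-amino-acid precursors (name ->
    (yield per substrate, biomass coefficient)), untouched by the basal-level
    scaling.
    """

    yields: dict[str, float]
    biomass_composition: dict[str, float]
    substrate_uptake: float = 10.0
    extra_biomass_components: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.yields) < 2:
            raise ValueError("need at least 2 amino acids")
        if any(v <= 0 for v in self.yields.values()):
            raise ValueError("yields must be positive")
        if self.substrate_uptake <= 0:
            raise ValueError("substrate uptake must be positive")
        if set(self.biomass_composition) - set(self.yields):
            raise ValueError("biomass references an amino acid without a synthesis reaction")

    @property
    def alphabet(self) -> list[str]:
        return list(self.yields)

    @property
    def cheapest(self) -> str:
        return max(self.yields, key=lambda a: self.yields[a])


def toy1_spec() -> ToyModelSpec:
    """The canonical two-amino-acid fixture with hand-derived optima."""
    return ToyModelSpec(
        yields={"A": 2.0, "B": 1.0},
        biomass_composition={"A": 1.0, "B": 1.0},
        substrate_uptake=10.0,
    )


def build_toy_model(spec: ToyModelSpec, model_id: str = "toy") -> StoichiometricModel:
    """Materialise a toy spec as a stoichiometric model with deterministic ids.

    Reactions: ``EX_substrate`` (exchange, lb = -uptake), one ``synth_<aa>``
    per amino acid (1 substrate -> yield * aa), and ``biomass``.
    """
    mets = [Metabolite("substrate", "carbon substrate", "c")]
    mets += [Metabolite(f"aa_{a}", f"amino acid {a}", "c") for a in spec.yields]
    mets += [Metabolite(f"x_{name}", name, "c") for name in spec.extra_biomass_components]
    rxns = [
        Reaction(
            "EX_substrate",
            {"substrate": -1.0},
            lower_bound=-spec.substrate_uptake,
            upper_bound=_RXN_UB,
        )
    ]
    for a, y in spec.yields.items():
        rxns.append(Reaction(f"synth_{a}", {"substrate": -1.0, f"aa_{a}": float(y)}, 0.0, _RXN_UB))
    for name, (y, _) in spec.extra_biomass_components.items():
        rxns.append(
            Reaction(f"synth_{name}", {"substrate": -1.0, f"x_{name}": float(y)}, 0.0, _RXN_UB)
        )
    biomass_stoich: dict[str, float] = {
        f"aa_{a}": -float(c) for a, c in spec.biomass_composition.items()
    }
    for name, (_, coef) in spec.extra_biomass_components.items():
        biomass_stoich[f"x_{name}"] = -float(coef)
    rxns.append(Reaction("biomass", biomass_stoich, 0.0, _RXN_UB))
    return StoichiometricModel(metabolites=mets, reactions=rxns, biomass_id="biomass", id=model_id)


def toy_aa_map(spec: ToyModelSpec) -> AminoAcidMap:
    return AminoAcidMap({a: f"aa_{a}" for a in spec.yields})


def random_toy_spec(rng: np.random.Generator) -> ToyModelSpec:
    """A random toy network: 2-6 amino acids, random yields, composition, uptake."""
    n_aa = int(rng.integers(2, 7))
    alphabet = list(string.ascii_uppercase[:n_aa])
    yields = {a: float(rng.uniform(0.5, 3.0)) for a in alphabet}
    composition = {a: float(rng.uniform(0.2, 2.0)) for a in alphabet}
    extra = {}
    if rng.random() < 0.5:
        extra["atp"] = (float(rng.uniform(1.0, 4.0)), float(rng.uniform(0.5, 3.0)))
    return ToyModelSpec(
        yields=yields,
        biomass_composition=composition,
        substrate_uptake=float(rng.uniform(5.0, 20.0)),
        extra_biomass_components=extra,
    )


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------


def gen_proteome(
    n: int,
    composition_bias: float,
    seed: int,
    spec: ToyModelSpec | None = None,
    length: int = DEFAULT_PROTEIN_LENGTH,
) -> list[ProteinRecord]:
    """Random fixed-length proteins over a toy model's amino-acid alphabet.

    Per-protein compositions are Dirichlet(1) draws (wide supply spread)
    interpolated toward a point mass on the cheapest residue by
    ``composition_bias`` in [0, 1]: bias 0 gives mean-uniform composition,
    bias 1 makes every sequence pure cheapest residue.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= composition_bias <= 1.0):
        raise ValueError("composition_bias must lie in [0, 1]")
    if spec is None:
        spec = toy1_spec()
    rng = np.random.default_rng(seed)
    alphabet = np.array(spec.alphabet)
    onehot = (alphabet == spec.cheapest).astype(float)
    records = []
    for k in range(n):
        p = (1.0 - composition_bias) * rng.dirichlet(np.ones(len(alphabet)))
        p = p + composition_bias * onehot
        p = p / p.sum()
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        counts = {a: seq.count(a) for a in alphabet if a in seq}
        freq = {a: c / length for a, c in counts.items()}
        records.append(ProteinRecord(id=f"g{k:05d}", sequence=seq, aa_freq=freq))
    return records


# ---------------------------------------------------------------------------
# expression tables with a planted Spearman structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedParams:
    """Planted statistical structure of a synthetic expression dataset.

    ``target_spearman_supply_te`` is the *population* Spearman correlation
    between supply and translation efficiency; analogous targets couple
    supply to ribosome density and to mRNA level (the latter mirrors the
    weak supply-expression correlation real data show, and gives the
    RD-increased-genes comparison its planted signal).  ``replicate_cv`` is
    the lognormal coefficient of variation of replicate RPKMs;
    ``buffering_delta`` the excess median starvation fold change of the
    worst-supplied genes over the best-supplied ones.
    """

    target_spearman_supply_te: float
    replicate_cv: float
    buffering_delta: float
    n_genes: int
    seed: int
    target_spearman_supply_rd: float = 0.3
    target_spearman_supply_mrna: float = 0.2
    n_replicates: int = 2
    fc_noise_sigma: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "target_spearman_supply_te",
            "target_spearman_supply_rd",
            "target_spearman_supply_mrna",
        ):
            rho = getattr(self, name)
            if abs(rho) > 0.95:
                raise ValueError(f"{name}={rho} too close to +-1 for the noise model")
        if self.replicate_cv < 0 or self.buffering_delta < 0:
            raise ValueError("replicate_cv and buffering_delta must be >= 0")
        if self.n_genes < 3 or self.n_replicates < 1:
            raise ValueError("need n_genes >= 3 and n_replicates >= 1")


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Van der Waerden scores of the value ranks (ties get equal scores)."""
    ranks = stats.rankdata(values)
    return stats.norm.ppf(ranks / (len(values) + 1.0))


def _coupled_normal(z: np.ndarray, rho_s: float, rng: np.random.Generator) -> np.ndarray:
    """Standard normal vector whose population Spearman with z equals rho_s.

    Uses the bivariate-normal identity rho_spearman = (6/pi) asin(rho/2),
    inverted to the Pearson parameter rho = 2 sin(pi rho_s / 6).
    """
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    eps = rng.standard_normal(len(z))
    return rho_p * z + math.sqrt(1.0 - rho_p**2) * eps


def _replicates(true: np.ndarray, cv: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """(n, k) replicate matrix with unit-mean lognormal noise of the given CV."""
    if cv == 0:
        return np.tile(true[:, None], (1, k))
    sigma = math.sqrt(math.log(1.0 + cv**2))
    noise = rng.standard_normal((len(true), k))
    return true[:, None] * np.exp(sigma * noise - sigma**2 / 2.0)


def gen_expression(supplies, params: PlantedParams) -> pd.DataFrame:
    """Synthetic expression tables coupled to a supply vector by Gaussian copula.

    ``supplies`` is an array of per-gene supply values (or a list of
    ``SupplyResult``); its length must equal ``params.n_genes``.  Columns:
    ``gene_id, supply, mrna_level, protein_abundance, te_true, rd_true``
    plus ``footprint_rpkm_rep<j>`` and ``mrna_rpkm_rep<j>``.
    """
    if hasattr(supplies[0], "supply"):
        gene_ids = [s.protein_id for s in supplies]
        supply = np.array([s.supply for s in supplies], dtype=float)
    else:
        supply = np.asarray(supplies, dtype=float)
        gene_ids = [f"g{k:05d}" for k in range(len(supply))]
    if len(supply) != params.n_genes:
        raise ValueError(f"{len(supply)} supplies for n_genes={params.n_genes}")
    if np.isnan(supply).any():
        raise ValueError("missing supply values")
    rng = np.random.default_rng(params.seed)
    z_s = _normal_scores(supply)

    te = 25.0 * np.exp(0.8 * _coupled_normal(z_s, params.target_spearman_supply_te, rng))
    mrna_level = 10.0 * np.exp(
        0.7 * _coupled_normal(z_s, params.target_spearman_supply_mrna, rng)
    )
    rd = 1.1 * np.exp(0.35 * _coupled_normal(z_s, params.target_spearman_supply_rd, rng))
    protein = te * mrna_level
    mrna_rpkm_true = 8.0 * mrna_level  # RPKM tracks molecules/cell on a different scale
    fp_rpkm_true = rd * mrna_rpkm_true

    fp_reps = _replicates(fp_rpkm_true, params.replicate_cv, params.n_replicates, rng)
    mr_reps = _replicates(mrna_rpkm_true, params.replicate_cv, params.n_replicates, rng)

    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "supply": supply,
            "mrna_level": mrna_level,
            "protein_abundance": protein,
            "te_true": te,
            "rd_true": rd,
        }
    )
    for j in range(params.n_replicates):
        out[f"footprint_rpkm_rep{j + 1}"] = fp_reps[:, j]
        out[f"mrna_rpkm_rep{j + 1}"] = mr_reps[:, j]
    return out


def expression_records(table: pd.DataFrame):
    """Convert a generated expression table to ``ExpressionRecord`` objects."""
    from .expression_metrics import ExpressionRecord

    fp_cols = sorted(c for c in table.columns if c.startswith("footprint_rpkm_rep"))
    mr_cols = sorted(c for c in table.columns if c.startswith("mrna_rpkm_rep"))
    return [
        ExpressionRecord(
            gene_id=row["gene_id"],
            mrna_level=float(row["mrna_level"]),
            protein_abundance=float(row["protein_abundance"]),
            footprint_rpkm=[float(row[c]) for c in fp_cols],
            mrna_rpkm=[float(row[c]) for c in mr_cols],
        )
        for _, row in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# starvation fold changes with planted buffering
# ---------------------------------------------------------------------------


def gen_starvation(records: pd.DataFrame, params: PlantedParams) -> pd.DataFrame:
    """Starvation table whose fold-change median decreases with supply.

    ``records`` needs columns ``gene_id, supply, rd_normal`` (``rd_true`` is
    accepted as ``rd_normal``); ``mrna_level`` is carried through when
    present.  The fold change of gene i is
    ``(1 + delta * (1 - pct_i)) * exp(sigma * eps)`` with ``pct_i`` the
    supply percentile in [0, 1], so its median is exactly the planted
    location and ``delta = 0`` makes fold change independent of supply.
    """
    df = records.copy()
    if "rd_normal" not in df.columns:
        if "rd_true" not in df.columns:
            raise ValueError("records need an rd_normal (or rd_true) column")
        df = df.rename(columns={"rd_true": "rd_normal"})
    rng = np.random.default_rng(params.seed + 1)
    supply = df["supply"].to_numpy(dtype=float)
    n = len(df)
    pct = (stats.rankdata(supply) - 1.0) / max(n - 1, 1)
    median_fc = 1.0 + params.buffering_delta * (1.0 - pct)
    fc = median_fc * np.exp(params.fc_noise_sigma * rng.standard_normal(n))
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "rd_normal": df["rd_normal"].to_numpy(dtype=float),
            "rd_starved": df["rd_normal"].to_numpy(dtype=float) * fc,
            "fold_change": fc,
            "supply": supply,
        }
    )
    if "mrna_level" in df.columns:
        out["mrna_level"] = df["mrna_level"].to_numpy(dtype=float)
    return out
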