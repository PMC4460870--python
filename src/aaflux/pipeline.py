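"""End-to-end orchestration: file I/O, stage sequencing, summary report.

``run_all`` executes supply -> features -> metrics -> correlations/
regressions -> starvation on files named in a :class:`PipelineConfig`,
writing one TSV per stage plus a versioned JSON summary.  Outputs are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression_metrics import ExpressionRecord, build_gene_table, compute_metrics
from .model_core import StoichiometricModel, read_model, write_model_json
from .robust_stats import rank_regression, spearman
from .seq_features import ProteinRecord, protein_record
from .starvation_analysis import (
    compare_fold_changes,
    rd_increased_mrna_comparison,
    split_waas_paas,
)
from .supply_fba import AminoAcidMap, aa_map_from_names, ijo1366_aa_map, supply_table
from .synthetic_data import (
    PlantedParams,
    build_toy_model,
    gen_expression,
    gen_proteome,
    gen_starvation,
    expression_records,
    toy1_spec,
    toy_aa_map,
)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "run_all",
    "simulate_dataset",
    "read_proteome_fasta",
    "write_proteome_fasta",
    "read_expression_tsv",
    "resolve_aa_map",
    "SUMMARY_SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid pipeline configuration (missing file, bad parameter)."""


@dataclass
class PipelineConfig:
    model_path: str
    proteome_path: str
    expression_path: str
    output_dir: str
    starvation_path: str | None = None
    aa_map_path: str | None = None
    folding_energy_path: str | None = None
    beta: float = 0.3
    substrate_uptake: float = 10.0
    substrate_exchange_id: str | None = None
    apply_filters: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.beta <= 1.0):
            raise ConfigError(f"beta must be in (0, 1], got {self.beta}")
        for name in ("model_path", "proteome_path", "expression_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        for name in ("starvation_path", "aa_map_path", "folding_energy_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_proteome_fasta(path: str, alphabet: set[str] | None = None) -> list[ProteinRecord]:
    from Bio import SeqIO

    records = [
        protein_record(rec.id, str(rec.seq), alphabet=alphabet, strict=False)
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path!r}")
    return records


def write_proteome_fasta(records: list[ProteinRecord], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records], path, "fasta"
    )


def read_expression_tsv(path: str) -> list[ExpressionRecord]:
    """Expression table with named headers.

    Required column ``gene_id``; optional ``mrna_level`` (molecules/cell) and
    ``protein_abundance`` (ppm); replicate series in columns named
    ``footprint_rpkm_rep<k>`` and ``mrna_rpkm_rep<k>``.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path!r}: missing gene_id column")
    fp_cols = sorted(c for c in df.columns if c.startswith("footprint_rpkm_rep"))
    mr_cols = sorted(c for c in df.columns if c.startswith("mrna_rpkm_rep"))

    def _opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    return [
        ExpressionRecord(
            gene_id=str(row["gene_id"]),
            mrna_level=_opt(row, "mrna_level"),
            protein_abundance=_opt(row, "protein_abundance"),
            footprint_rpkm=[float(row[c]) for c in fp_cols if not pd.isna(row[c])],
            mrna_rpkm=[float(row[c]) for c in mr_cols if not pd.isna(row[c])],
        )
        for _, row in df.iterrows()
    ]


def read_aa_map(path: str) -> AminoAcidMap:
    """TSV with columns ``code`` and ``metabolite_id`` (or a JSON object)."""
    if str(path).endswith(".json"):
        with open(path) as fh:
            return AminoAcidMap(json.load(fh))
    df = pd.read_csv(path, sep="\t")
    return AminoAcidMap(dict(zip(df["code"].astype(str), df["metabolite_id"].astype(str))))


def resolve_aa_map(model: StoichiometricModel, path: str | None = None) -> AminoAcidMap:
    """Amino-acid map from a file, or inferred from the model.

    Inference order: toy convention (metabolite ids ``aa_<code>``), the
    shipped iJO1366 BiGG-id map, then chemical-name matching (yeast-style
    models with opaque ids).
    """
    if path is not None:
        amap = read_aa_map(path)
        amap.validate(model)
        return amap
    toy = {
        m.id[3:]: m.id
        for m in model.metabolites
        if m.id.startswith("aa_") and len(m.id) == 4
    }
    if toy:
        return AminoAcidMap(toy)
    try:
        amap = ijo1366_aa_map()
        amap.validate(model, require_all_20=True)
        return amap
    except ValueError:
        pass
    return aa_map_from_names(model)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _correlation_entry(res) -> dict:
    return {"r": res.r, "p_value": res.p_value, "n": res.n, "ok": res.ok}


def _fit_entry(fit) -> dict:
    return {
        "coefficients": fit.coefficients,
        "intercept": fit.intercept,
        "p_values": fit.p_values,
        "total_r": fit.total_r,
        "total_r_definition": fit.total_r_definition,
        "dispersion_full": fit.dispersion_full,
        "dispersion_null": fit.dispersion_null,
        "n": fit.n,
    }


def _comparison_entry(cmp) -> dict:
    return {
        "groups": [cmp.group_a_label, cmp.group_b_label],
        "medians": [cmp.median_a, cmp.median_b],
        "n": [cmp.n_a, cmp.n_b],
        "p_value": cmp.p_value,
        "alternative": cmp.alternative,
        "empty_group": cmp.empty_group,
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the summary dict also written to JSON.

    Any stage failure raises with the stage name attached; outputs written
    before the failure are retained for inspection.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        model = read_model(config.model_path)
        aa_map = resolve_aa_map(model, config.aa_map_path)
        proteome = read_proteome_fasta(config.proteome_path, alphabet=set(aa_map.codes()))
        records = read_expression_tsv(config.expression_path)

        stage = "supply"
        supplies = supply_table(
            model,
            aa_map,
            proteome,
            beta=config.beta,
            substrate_uptake=config.substrate_uptake,
            substrate_exchange_id=config.substrate_exchange_id,
        )
        supply_df = pd.DataFrame(
            {
                "protein_id": [s.protein_id for s in supplies],
                "supply": [s.supply for s in supplies],
                "mu": [s.mu for s in supplies],
                "beta": [s.basal_level for s in supplies],
            }
        )
        supply_df.to_csv(out / "supply.tsv", sep="\t", index=False)

        stage = "metrics"
        metrics = compute_metrics(records)
        metrics_df = pd.DataFrame(
            {
                "gene_id": [m.gene_id for m in metrics],
                "te": [m.te for m in metrics],
                "rd": [m.rd for m in metrics],
                "passed_te_filter": [m.passed_te_filter for m in metrics],
                "passed_rd_filter": [m.passed_rd_filter for m in metrics],
            }
        )
        metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False)

        stage = "gene_table"
        table = build_gene_table(supply_df[["protein_id", "supply"]], metrics_df)
        table.to_csv(out / "gene_table.tsv", sep="\t", index=False)

        stage = "correlate"
        if config.apply_filters:
            te_rows = table[table["passed_te_filter"] & table["te"].notna()]
            rd_rows = table[table["passed_rd_filter"] & table["rd"].notna()]
        else:
            te_rows = table[table["te"].notna()]
            rd_rows = table[table["rd"].notna()]
        correlations = {
            "supply_te": _correlation_entry(spearman(te_rows["supply"], te_rows["te"])),
            "supply_rd": _correlation_entry(spearman(rd_rows["supply"], rd_rows["rd"])),
        }

        stage = "regress"
        reg_rd_rows = rd_rows.dropna(subset=["supply", "rd"])
        fit_rd = rank_regression(reg_rd_rows[["supply"]], reg_rd_rows["rd"].to_numpy())
        both = table[table["te"].notna() & table["rd"].notna()]
        if config.apply_filters:
            both = both[both["passed_te_filter"] & both["passed_rd_filter"]]
        fit_te = rank_regression(both[["supply", "rd"]], both["te"].to_numpy())
        regressions = {"rd~supply": _fit_entry(fit_rd), "te~supply+rd": _fit_entry(fit_te)}

        starvation = None
        if config.starvation_path is not None:
            stage = "starvation"
            sdf = pd.read_csv(config.starvation_path, sep="\t")
            if "fold_change" not in sdf.columns:
                sdf["fold_change"] = sdf["rd_starved"] / sdf["rd_normal"]
            sdf.to_csv(out / "starvation.tsv", sep="\t", index=False)
            waas, paas = split_waas_paas(sdf)
            starvation = {
                "waas_vs_paas": _comparison_entry(compare_fold_changes(waas, paas)),
            }
            if "mrna_level" in sdf.columns:
                starvation["rd_increased_mrna"] = _comparison_entry(
                    rd_increased_mrna_comparison(sdf)
                )

        stage = "summary"
        summary = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "aaflux_version": __version__,
            "config": {
                "beta": config.beta,
                "substrate_uptake": config.substrate_uptake,
                "apply_filters": config.apply_filters,
                "seed": config.seed,
                "cai_dialect": "sharp-li",
                "rpkm_filter": "mean>1 and max/min<1.5, both series, strict",
                "mrna_filter": "mrna_level>0.5 molecules/cell, strict",
                "waas_split": "top 50% supply, larger group on odd n, ties to WAAS",
            },
            "n_proteins": len(supplies),
            "n_genes_joined": len(table),
            "mu": supplies[0].mu if supplies else None,
            "correlations": correlations,
            "regressions": regressions,
            "starvation": starvation,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return summary
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# simulate preset
# ---------------------------------------------------------------------------


def simulate_dataset(
    out_dir: str,
    seed: int,
    preset: str = "toy1",
    n_genes: int = 500,
    target_spearman: float = 0.30,
    replicate_cv: float = 0.1,
    buffering_delta: float = 0.2,
    composition_bias: float = 0.2,
    beta: float = 0.3,
) -> PipelineConfig:
    """Write a complete synthetic dataset and the config that consumes it.

    Produces ``model.json``, ``proteome.fasta``, ``expression.tsv``,
    ``starvation.tsv`` and ``config.toml`` under ``out_dir``.
    """
    if preset != "toy1":
        raise ConfigError(f"unknown preset {preset!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = toy1_spec()
    model = build_toy_model(spec)
    write_model_json(model, str(out / "model.json"))
    proteome = gen_proteome(n_genes, composition_bias, seed, spec=spec)
    write_proteome_fasta(proteome, str(out / "proteome.fasta"))

    supplies = supply_table(model, toy_aa_map(spec), proteome, beta=beta)
    params = PlantedParams(
        target_spearman_supply_te=target_spearman,
        replicate_cv=replicate_cv,
        buffering_delta=buffering_delta,
        n_genes=n_genes,
        seed=seed,
    )
    expr = gen_expression(supplies, params)
    cols = ["gene_id", "mrna_level", "protein_abundance"] + [
        c for c in expr.columns if "_rpkm_rep" in c
    ]
    expr[cols].to_csv(out / "expression.tsv", sep="\t", index=False)

    starv = gen_starvation(expr, params)
    starv.to_csv(out / "starvation.tsv", sep="\t", index=False)

    config = PipelineConfig(
        model_path=str(out / "model.json"),
        proteome_path=str(out / "proteome.fasta"),
        expression_path=str(out / "expression.tsv"),
        starvation_path=str(out / "starvation.tsv"),
        output_dir=str(out / "results"),
        beta=beta,
        seed=seed,
    )
    with open(out / "config.toml", "w") as fh:
        for f in dataclasses.fields(config):
            v = getattr(config, f.name)
            if v is None:
                continue
            if isinstance(v, bool):
                fh.write(f"{f.name} = {'true' if v else 'false'}\n")
            elif isinstance(v, (int, float)):
                fh.write(f"{f.name} = {v}\n")
            else:
                fh.write(f'{f.name} = "{v}"\n')
    return config
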