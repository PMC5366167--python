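"""Readers and writers for genotype, phenotype, map, effects and report files.

Two genotype dialects are supported: a comma-delimited matrix with a header
row of marker IDs and the individual ID in the first column, and a PLINK
.raw-style dosage file (whitespace-delimited, six leading columns FID IID
PAT MAT SEX PHENOTYPE followed by one dosage column per SNP).  Rows are
individuals in both.  Dosages must be 0/1/2; missing values are rejected
rather than imputed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, InvalidInputError, PosteriorSummary
from .simulate import GeneticMap, Locus, SimulatedPopulation

PLINK_LEADING = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _validate_cells(values: pd.DataFrame, path) -> np.ndarray:
    numeric = values.apply(pd.to_numeric, errors="coerce")
    arr = numeric.to_numpy(dtype=np.float64)
    bad = np.isnan(arr)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidInputError(
            f"{path}: missing or non-numeric genotype at row {r + 1}, column "
            f"'{values.columns[c]}' (imputation is not supported)"
        )
    ok = np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise InvalidInputError(
            f"{path}: genotype value {arr[r, c]!r} at row {r + 1}, column "
            f"'{values.columns[c]}' is not 0/1/2"
        )
    return arr.astype(np.int8)


def read_genotype_table(path, dialect: str = "matrix-csv") -> GenotypeMatrix:
    """Read an n x p dosage matrix in the 'matrix-csv' or 'plink-raw' dialect."""
    path = Path(path)
    if dialect == "matrix-csv":
        df = pd.read_csv(path, index_col=0)
        ids = [str(i) for i in df.index]
        markers = [str(c) for c in df.columns]
    elif dialect == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+")
        if df.shape[1] < 7:
            raise InvalidInputError(
                f"{path}: plink-raw needs 6 leading columns plus at least one SNP"
            )
        ids = [str(i) for i in df.iloc[:, 1]]
        markers = [str(c) for c in df.columns[6:]]
        df = df.iloc[:, 6:]
    else:
        raise InvalidInputError(f"unknown genotype dialect '{dialect}'")
    if len(set(ids)) != len(ids):
        raise InvalidInputError(f"{path}: duplicate individual IDs")
    if len(set(markers)) != len(markers):
        raise InvalidInputError(f"{path}: duplicate marker IDs")
    values = _validate_cells(df, path)
    return GenotypeMatrix(values, tuple(markers), tuple(ids))


def write_genotype_table(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.values,
        index=list(genotypes.individual_ids),
        columns=list(genotypes.marker_ids),
    )
    df.index.name = "id"
    df.to_csv(path)


def read_phenotypes(path, individual_ids=None) -> pd.Series:
    """Read a two-column (id, value) delimited file.

    With ``individual_ids`` the values are realigned to that order; any
    individual without a phenotype is an error (offenders are listed).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise InvalidInputError(f"{path}: expected two columns (id, value)")
    ids = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2  # header + 1-based
        raise InvalidInputError(f"{path}: non-numeric phenotype on line {line}")
    if ids.duplicated().any():
        raise InvalidInputError(f"{path}: duplicate individual IDs")
    series = pd.Series(vals.to_numpy(), index=ids.to_numpy(), name="phenotype")
    if individual_ids is not None:
        missing = [i for i in individual_ids if i not in series.index]
        if missing:
            raise InvalidInputError(
                f"{path}: no phenotype for individuals: {', '.join(missing[:10])}"
            )
        series = series.loc[list(individual_ids)]
    return series


def write_phenotypes(phenotypes, individual_ids, path) -> None:
    pd.DataFrame(
        {"id": list(individual_ids), "phenotype": np.asarray(phenotypes)}
    ).to_csv(path, index=False)


def write_map(gmap: GeneticMap, path) -> None:
    pd.DataFrame(
        {
            "chromosome": [l.chromosome for l in gmap.loci],
            "position_cM": [l.position_cm for l in gmap.loci],
            "locus_id": [l.locus_id for l in gmap.loci],
            "is_qtl": [int(l.is_qtl) for l in gmap.loci],
        }
    ).to_csv(path, index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path)
    loci = tuple(
        Locus(int(r.chromosome), float(r.position_cM), str(r.locus_id), bool(r.is_qtl))
        for r in df.itertuples()
    )
    return GeneticMap(loci)


def write_population(pop: SimulatedPopulation, out_dir) -> dict:
    """Write genotypes, phenotypes and map of a simulated panel; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.csv",
        "phenotypes": out / "phenotypes.csv",
        "map": out / "map.csv",
    }
    write_genotype_table(pop.marker_genotypes, paths["genotypes"])
    write_phenotypes(pop.phenotypes, pop.marker_genotypes.individual_ids,
                     paths["phenotypes"])
    write_map(pop.genetic_map, paths["map"])
    return paths


def _config_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_outputs(summary: PosteriorSummary, metrics, out_dir, config=None) -> dict:
    """Write the marker-effects table, a structured metrics report and a
    config echo sufficient to reproduce the run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    effects_path = out / "marker_effects.csv"
    pd.DataFrame(
        {
            "marker_id": list(summary.marker_ids),
            "posterior_mean_effect": np.asarray(summary.b_mean, dtype=np.float64),
        }
    ).to_csv(effects_path, index=False, float_format="%.17g")

    report = {
        "mu_mean": summary.mu_mean,
        "var_b_mean": summary.var_b_mean,
        "var_e_mean": summary.var_e_mean,
        "op_count": summary.diagnostics["op_count"],
        "seed": summary.diagnostics["seed"],
        "n": summary.diagnostics["n"],
        "p": summary.diagnostics["p"],
    }
    if metrics is not None:
        report["metrics"] = {
            "predictive_ability": metrics.predictive_ability,
            "mspe": metrics.mspe,
            "bias_slope": metrics.bias_slope,
            "op_count": metrics.op_count,
            "wall_minutes": metrics.wall_minutes,
        }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n")

    echo_path = out / "config_echo.json"
    echo = _config_to_dict(config if config is not None
                           else summary.diagnostics["config"])
    echo_path.write_text(json.dumps(echo, indent=2) + "\n")
    return {"effects": effects_path, "report": report_path, "config": echo_path}
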