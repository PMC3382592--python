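"""TSV/JSON readers and writers for the mapping pipeline.

Canonical tabular dialect: UTF-8 TSV with ``NA`` as the missing token
(breeding-data convention).  Marker map positions are 1-based physical bp
and only order HTL names.  All writers emit deterministic column order so
reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diallel_core import DiallelDesign, FounderGenotypeMatrix, MarkerDef
from .heterosis import REQUIRED_PHENO_COLUMNS
from .scan import ScanResult

SCHEMA_VERSION = "1.0"
NA = "NA"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=True, dtype=str)


def read_founder_genotypes(
    path, marker_map: Optional[Sequence[MarkerDef]] = None
) -> FounderGenotypeMatrix:
    """Wide founder x marker TSV: first column founder id, cells allele sizes."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected founder id column plus markers")
    idcol = raw.columns[0]
    if raw[idcol].duplicated().any():
        dup = raw.loc[raw[idcol].duplicated(), idcol].tolist()
        raise ValueError(f"{path}: duplicate founder ids {dup}")
    calls = raw.set_index(idcol)
    for col in calls.columns:
        for line_offset, v in enumerate(calls[col]):
            if pd.isna(v):
                continue
            try:
                int(float(v))
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer allele {v!r} in column {col}, "
                    f"line {line_offset + 2}"
                ) from None
    calls = calls.astype(float)
    return FounderGenotypeMatrix(calls, markers=marker_map)


def write_founder_genotypes(geno: FounderGenotypeMatrix, path) -> None:
    out = geno.calls.copy()
    out = out.map(lambda v: NA if pd.isna(v) else str(int(v)))
    out.index.name = "founder"
    out.to_csv(path, sep="\t")


def read_marker_map(path) -> list[MarkerDef]:
    """Marker map TSV: marker, chromosome, position (1-based bp)."""
    df = _read_tsv(path)
    req = {"marker", "chromosome", "position"}
    if not req <= set(df.columns):
        raise ValueError(f"{path}: marker map needs columns {sorted(req)}")
    out = []
    for _, row in df.iterrows():
        pos = None if pd.isna(row["position"]) else float(row["position"])
        out.append(MarkerDef(row["marker"], str(row["chromosome"]), pos))
    return out


def write_marker_map(markers: Sequence[MarkerDef], path) -> None:
    pd.DataFrame(
        {
            "marker": [m.name for m in markers],
            "chromosome": [m.chromosome for m in markers],
            "position": [
                NA if m.position is None else int(m.position) for m in markers
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_design(path) -> DiallelDesign:
    """Design TSV: cross_id, female, male [, year]."""
    df = _read_tsv(path)
    return DiallelDesign(df)


def write_design(design: DiallelDesign, path) -> None:
    cols = [c for c in ("cross_id", "female", "male", "year") if c in design.crosses]
    design.crosses[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path, traits: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Long phenotype TSV: entry, year, replicate, one column per trait."""
    df = _read_tsv(path)
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {missing}")
    trait_cols = [c for c in df.columns if c not in REQUIRED_PHENO_COLUMNS]
    if traits is not None:
        trait_cols = [c for c in trait_cols if c in traits]
        absent = [t for t in traits if t not in df.columns]
        if absent:
            raise ValueError(f"{path}: trait columns absent {absent}")
    df["replicate"] = df["replicate"].astype(int)
    for t in trait_cols:
        try:
            df[t] = df[t].astype(float)
        except ValueError as e:
            raise ValueError(f"{path}: non-numeric value in trait column {t}: {e}")
    return df[["entry", "year", "replicate", *trait_cols]]


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_clusters(path) -> dict:
    """Cluster TSV: founder, cluster."""
    df = _read_tsv(path)
    if not {"founder", "cluster"} <= set(df.columns):
        raise ValueError(f"{path}: cluster table needs columns founder, cluster")
    if df["founder"].duplicated().any():
        raise ValueError(f"{path}: duplicate founder rows")
    return dict(zip(df["founder"], df["cluster"]))


def write_clusters(assign: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"founder": list(assign), "cluster": [assign[f] for f in assign]}
    ).to_csv(path, sep="\t", index=False)


def read_f2(path, trait: Optional[str] = None) -> pd.DataFrame:
    """F2 TSV: plant, genotype (allele1/allele2), trait columns."""
    df = _read_tsv(path)
    if not {"plant", "genotype"} <= set(df.columns):
        raise ValueError(f"{path}: F2 table needs columns plant, genotype")
    for c in df.columns:
        if c in ("plant", "genotype"):
            continue
        if trait is None or c == trait:
            df[c] = df[c].astype(float)
    return df


def write_odh_table(odh: pd.DataFrame, path) -> None:
    odh.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_odh_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for c in ("R",):
        df[c] = df[c].astype(int)
    for c in ("ODH", "MPH", "BPH"):
        df[c] = df[c].astype(float)
    df["flag"] = df["flag"].fillna("")
    return df


def scan_table(result: ScanResult) -> pd.DataFrame:
    """Flatten a ScanResult: one row per marker/year plus per hetero pair."""
    rows = []
    for year, results in result.years.items():
        for r in results:
            base = {
                "marker": r.marker, "year": year, "trait": result.trait,
                "F": r.F, "p": r.p, "threshold": r.threshold,
                "passed": r.passed, "skip_reason": r.skip_reason or "",
                "pair": "", "n_hetero": "", "n_homo": "",
                "D": np.nan, "ks_p": np.nan, "advantage": "",
            }
            if not r.step2:
                rows.append(base)
            for pair, ks in sorted(r.step2.items()):
                rows.append(
                    {
                        **base,
                        "pair": f"{pair[0]}/{pair[1]}",
                        "n_hetero": ks.n_hetero, "n_homo": ks.n_homo,
                        "D": ks.D, "ks_p": ks.p, "advantage": ks.advantage,
                    }
                )
    return pd.DataFrame(rows)


def htl_calls_json(result: ScanResult, config=None) -> dict:
    calls = []
    for c in result.calls:
        calls.append(
            {
                "name": c.name,
                "marker": c.marker,
                "trait": c.trait,
                "chromosome": c.chromosome,
                "position": c.position,
                "pairs": [list(p) for p in c.pairs],
                "per_year": {
                    str(y): {
                        f"{p[0]}/{p[1]}": {
                            "D": ks.D, "p": ks.p, "advantage": ks.advantage,
                            "n_hetero": ks.n_hetero, "n_homo": ks.n_homo,
                        }
                        for p, ks in yr.items()
                    }
                    for y, yr in c.per_year.items()
                },
            }
        )
    doc = {
        "schema_version": SCHEMA_VERSION,
        "trait": result.trait,
        "thresholds": {str(y): t for y, t in result.thresholds.items()},
        "n_markers": len(next(iter(result.years.values()))) if result.years else 0,
        "calls": calls,
    }
    if config is not None:
        doc["config"] = {k: getattr(config, k) for k in vars(config)}
    return doc


def write_reports(result: ScanResult, out_dir, config=None) -> dict:
    """Write scan TSV + HTL JSON (+ run log) into ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan_path = out / "scan.tsv"
    scan_table(result).to_csv(
        scan_path, sep="\t", index=False, na_rep=NA, float_format="%.6g"
    )
    calls_path = out / "htl_calls.json"
    doc = htl_calls_json(result, config=config)
    calls_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    log_path = out / "run_log.json"
    log = {
        "schema_version": SCHEMA_VERSION,
        "seed": getattr(config, "seed", None) if config is not None else None,
        "config_hash": hashlib.sha256(
            json.dumps(doc.get("config", {}), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_calls": len(result.calls),
    }
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {"scan": scan_path, "calls": calls_path, "log": log_path}
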