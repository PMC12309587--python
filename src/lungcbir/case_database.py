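"""Case registry with population z-score normalization.

Cases enter the database as raw per-region feature vectors.  Before any
search, per-slot normalization statistics — the mean and (population)
standard deviation of every (region, feature) slot across all registered
cases — are computed, and features are compared as z-scores against those
statistics.  A query is normalized with the *database's* statistics and is
never part of them, matching a leave-one-out evaluation protocol.

Zero-deviation slots (a feature constant across the whole database) carry no
information and are mapped to z = 0.

The on-disk layout is a directory of plain-text files::

    cases.csv      one row per case, columns L{level}_{region}_F{nn} + LES_{region}
    labels.csv     case_id, ILD, UIP, diagnosis
    stats.csv      slot, mean, std            (present once computed)
    manifest.json  schema version, case count
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .feature_extraction import CaseFeatures, N_COARSE_FEATURES, N_FINE_FEATURES
from .region_partition import ALL_REGION_NAMES, COARSE_NAMES, LEVEL3_NAMES

__all__ = [
    "RegistrationError",
    "NormalizationStats",
    "NormalizedCase",
    "CaseDatabase",
    "feature_columns",
    "cases_to_frame",
    "cases_from_frame",
]

_SCHEMA_VERSION = "1.0"

_COARSE_LEVEL = {name: (0 if name == "whole" else 1 if name in ("right", "left") else 2) for name in COARSE_NAMES}


def feature_columns() -> list[str]:
    """Flat column order used by cases.csv and stats.csv."""
    cols = [
        f"L{_COARSE_LEVEL[r]}_{r}_F{n + 1:02d}"
        for r in COARSE_NAMES
        for n in range(N_COARSE_FEATURES)
    ]
    cols += [f"L3_{r}_F{n + 1:02d}" for r in LEVEL3_NAMES for n in range(N_FINE_FEATURES)]
    cols += [f"LES_{r}" for r in ALL_REGION_NAMES]
    return cols


_COLUMNS = feature_columns()
_N_COARSE = len(COARSE_NAMES) * N_COARSE_FEATURES
_N_FINE = len(LEVEL3_NAMES) * N_FINE_FEATURES


class RegistrationError(ValueError):
    """Invalid registration (e.g. duplicate case id)."""


@dataclass
class NormalizationStats:
    """Per-slot mean and population standard deviation over the registered
    cases (separately for the coarse (9, 12) and fine (24, 30) blocks)."""

    coarse_mean: np.ndarray
    coarse_std: np.ndarray
    fine_mean: np.ndarray
    fine_std: np.ndarray
    n_cases: int


@dataclass
class NormalizedCase:
    """A case's z-scored feature blocks, paired with its raw features (the
    similarity weights are functions of the raw proportions)."""

    raw: CaseFeatures
    coarse_z: np.ndarray
    fine_z: np.ndarray


def _flatten(case: CaseFeatures) -> np.ndarray:
    return np.concatenate([case.coarse.ravel(), case.fine.ravel(), case.lesion])


def _unflatten(case_id: str, row: np.ndarray, labels: dict[str, str], diagnosis: str | None) -> CaseFeatures:
    coarse = row[:_N_COARSE].reshape(len(COARSE_NAMES), N_COARSE_FEATURES)
    fine = row[_N_COARSE : _N_COARSE + _N_FINE].reshape(len(LEVEL3_NAMES), N_FINE_FEATURES)
    lesion = row[_N_COARSE + _N_FINE :]
    return CaseFeatures(case_id, coarse, fine, lesion, labels=labels, diagnosis=diagnosis)


def cases_to_frame(cases: Iterable[CaseFeatures]) -> pd.DataFrame:
    """Standalone feature table: one row per case, features + label columns."""
    cases = list(cases)
    rows = np.stack([_flatten(c) for c in cases]) if cases else np.zeros((0, len(_COLUMNS)))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.insert(0, "case_id", [c.case_id for c in cases])
    df["ILD"] = [c.labels.get("ILD", "") for c in cases]
    df["UIP"] = [c.labels.get("UIP", "") for c in cases]
    df["diagnosis"] = [c.diagnosis or "" for c in cases]
    return df


def cases_from_frame(df: pd.DataFrame) -> list[CaseFeatures]:
    """Inverse of :func:`cases_to_frame`."""
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise RegistrationError(f"feature table lacks {len(missing)} expected columns, e.g. {missing[:3]}")
    out = []
    for _, row in df.iterrows():
        labels = {k: row[k] for k in ("ILD", "UIP") if k in df.columns and isinstance(row.get(k), str) and row[k]}
        diagnosis = row.get("diagnosis") if isinstance(row.get("diagnosis"), str) and row.get("diagnosis") else None
        out.append(_unflatten(str(row["case_id"]), row[_COLUMNS].to_numpy(dtype=np.float64), labels, diagnosis))
    return out


class CaseDatabase:
    """Registered cases + normalization statistics."""

    def __init__(self) -> None:
        self.cases: dict[str, CaseFeatures] = {}
        self.stats: NormalizationStats | None = None

    def __len__(self) -> int:
        return len(self.cases)

    def __contains__(self, case_id: str) -> bool:
        return case_id in self.cases

    # -- registration ------------------------------------------------------

    def register_case(self, case: CaseFeatures) -> None:
        """Store a case's raw features; statistics become stale."""
        if case.case_id in self.cases:
            raise RegistrationError(f"case id already registered: {case.case_id!r}")
        self.cases[case.case_id] = case
        self.stats = None  # stale until recomputed

    def register_all(self, cases: Iterable[CaseFeatures]) -> None:
        for case in cases:
            self.register_case(case)

    # -- statistics & normalization ---------------------------------------

    def compute_stats(self, exclude: Iterable[str] = ()) -> NormalizationStats:
        """Per-slot mean/std over registered cases (optionally excluding
        some, e.g. the query in a leave-one-out run).  Stores and returns
        the result; stored stats are only kept when nothing was excluded."""
        excluded = set(exclude)
        ids = [cid for cid in self.cases if cid not in excluded]
        if not ids:
            raise RegistrationError("cannot compute statistics over an empty database")
        coarse = np.stack([self.cases[c].coarse for c in ids])
        fine = np.stack([self.cases[c].fine for c in ids])

        def _std(block: np.ndarray, mean: np.ndarray) -> np.ndarray:
            sd = block.std(axis=0)
            # snap cancellation noise to an exact zero so the degenerate-slot
            # rule (z = 0) applies to constant slots
            return np.where(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)), 0.0, sd)

        cm, fm = coarse.mean(axis=0), fine.mean(axis=0)
        stats = NormalizationStats(
            coarse_mean=cm,
            coarse_std=_std(coarse, cm),
            fine_mean=fm,
            fine_std=_std(fine, fm),
            n_cases=len(ids),
        )
        if not excluded:
            self.stats = stats
        return stats

    @staticmethod
    def normalize(case: CaseFeatures, stats: NormalizationStats) -> NormalizedCase:
        """z = (x - mean)/std per slot; zero-deviation slots map to z = 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            cz = np.where(stats.coarse_std > 0, (case.coarse - stats.coarse_mean) / stats.coarse_std, 0.0)
            fz = np.where(stats.fine_std > 0, (case.fine - stats.fine_mean) / stats.fine_std, 0.0)
        return NormalizedCase(raw=case, coarse_z=cz, fine_z=fz)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ids = sorted(self.cases)
        rows = np.stack([_flatten(self.cases[c]) for c in ids]) if ids else np.zeros((0, len(_COLUMNS)))
        df = pd.DataFrame(rows, columns=_COLUMNS)
        df.insert(0, "case_id", ids)
        df.to_csv(directory / "cases.csv", index=False)

        labels = pd.DataFrame(
            {
                "case_id": ids,
                "ILD": [self.cases[c].labels.get("ILD", "") for c in ids],
                "UIP": [self.cases[c].labels.get("UIP", "") for c in ids],
                "diagnosis": [self.cases[c].diagnosis or "" for c in ids],
            }
        )
        labels.to_csv(directory / "labels.csv", index=False)

        if self.stats is not None:
            stats_df = pd.DataFrame(
                {
                    "slot": _COLUMNS[: _N_COARSE + _N_FINE],
                    "mean": np.concatenate([self.stats.coarse_mean.ravel(), self.stats.fine_mean.ravel()]),
                    "std": np.concatenate([self.stats.coarse_std.ravel(), self.stats.fine_std.ravel()]),
                }
            )
            stats_df.to_csv(directory / "stats.csv", index=False)

        manifest = {
            "format": "lungcbir-case-database",
            "schema_version": _SCHEMA_VERSION,
            "n_cases": len(ids),
            "has_stats": self.stats is not None,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "CaseDatabase":
        directory = Path(directory)
        db = cls()
        df = pd.read_csv(directory / "cases.csv", dtype={"case_id": str}, float_precision="round_trip")
        if list(df.columns[1:]) != _COLUMNS:
            raise RegistrationError(f"unexpected column layout in {directory / 'cases.csv'}")
        labels_df = pd.read_csv(directory / "labels.csv", dtype=str).fillna("")
        labels_map = {
            row["case_id"]: (
                {k: row[k] for k in ("ILD", "UIP") if row.get(k)},
                row.get("diagnosis") or None,
            )
            for _, row in labels_df.iterrows()
        }
        for _, row in df.iterrows():
            cid = row["case_id"]
            lab, diag = labels_map.get(cid, ({}, None))
            db.register_case(_unflatten(cid, row[_COLUMNS].to_numpy(dtype=np.float64), lab, diag))
        stats_path = directory / "stats.csv"
        if stats_path.exists():
            s = pd.read_csv(stats_path, float_precision="round_trip")
            mean = s["mean"].to_numpy()
            std = s["std"].to_numpy()
            db.stats = NormalizationStats(
                coarse_mean=mean[:_N_COARSE].reshape(len(COARSE_NAMES), N_COARSE_FEATURES),
                coarse_std=std[:_N_COARSE].reshape(len(COARSE_NAMES), N_COARSE_FEATURES),
                fine_mean=mean[_N_COARSE:].reshape(len(LEVEL3_NAMES), N_FINE_FEATURES),
                fine_std=std[_N_COARSE:].reshape(len(LEVEL3_NAMES), N_FINE_FEATURES),
                n_cases=len(db),
            )
        return db
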