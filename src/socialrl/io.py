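"""CSV and manifest I/O for trial tables, covariates, and fit results.

All tabular exchange is plain UTF-8 CSV with a header row.  Schemas:

* PRL trials:  ``participant_id,trial,choice,reward``
* DG trials:   ``participant_id,trial,partner_return,hi_rating,si_rating,condition``
* covariates:  ``participant_id,paranoia,icar,condition``
* fits:        flattened fit-result fields plus one column per estimate

Readers validate the header and report what was expected on mismatch.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fitting import FitResult
from .tasks import TrialRecordDG, TrialRecordPRL

PRL_COLUMNS = ["participant_id", "trial", "choice", "reward"]
DG_COLUMNS = ["participant_id", "trial", "partner_return", "hi_rating",
              "si_rating", "condition"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing columns {missing}; expected header {required}"
        )


def prl_records_to_df(
    records: Mapping[str, Sequence[TrialRecordPRL]]
) -> pd.DataFrame:
    rows = [
        {"participant_id": pid, "trial": r.trial, "choice": r.choice,
         "reward": r.reward}
        for pid, recs in records.items()
        for r in recs
    ]
    return pd.DataFrame(rows, columns=PRL_COLUMNS)


def df_to_prl_records(df: pd.DataFrame) -> dict[str, list[TrialRecordPRL]]:
    _check_columns(df, PRL_COLUMNS, "PRL trial table")
    out: dict[str, list[TrialRecordPRL]] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial")
        out[str(pid)] = [
            TrialRecordPRL(int(t), int(c), float(r))
            for t, c, r in zip(grp["trial"], grp["choice"], grp["reward"])
        ]
    return out


def dg_records_to_df(
    records: Mapping[str, Sequence[TrialRecordDG]],
    conditions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    conditions = conditions or {}
    rows = [
        {"participant_id": pid, "trial": r.trial,
         "partner_return": r.partner_return, "hi_rating": r.hi_rating,
         "si_rating": r.si_rating,
         "condition": conditions.get(pid, "")}
        for pid, recs in records.items()
        for r in recs
    ]
    return pd.DataFrame(rows, columns=DG_COLUMNS)


def df_to_dg_records(df: pd.DataFrame) -> dict[str, list[TrialRecordDG]]:
    _check_columns(df, DG_COLUMNS[:5], "DG trial table")
    out: dict[str, list[TrialRecordDG]] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial")
        out[str(pid)] = [
            TrialRecordDG(int(t), float(pr), float(hi), float(si))
            for t, pr, hi, si in zip(
                grp["trial"], grp["partner_return"],
                grp["hi_rating"], grp["si_rating"],
            )
        ]
    return out


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table with full float precision so round trips are lossless."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a table with round-trip float parsing (exact inverse of write_csv)."""
    return pd.read_csv(path, float_precision="round_trip")


def read_prl_trials(path: str | Path) -> dict[str, list[TrialRecordPRL]]:
    return df_to_prl_records(read_csv(path))


def read_dg_trials(path: str | Path) -> dict[str, list[TrialRecordDG]]:
    return df_to_dg_records(read_csv(path))


def fits_to_df(fits: Iterable[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in fits])


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path, config: Mapping, seed: int, files: Sequence[str]
) -> Path:
    """One manifest per output directory: config snapshot, seed, checksums."""
    out_dir = Path(out_dir)
    manifest = {
        "package": "socialrl",
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": dict(config),
        "checksums": {f: file_checksum(out_dir / f) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
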