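"""Judgment-count CSV files, JSON artifacts, and configs.

The judgment CSV is wide (one row per SOA, counts rather than trials)
because every model likelihood here is binomial at the SOA level::

    participant,condition,soa_ms,n_trials,n_probe_first

SOAs must be unique within a (participant, condition) cell, counts must not
exceed trial numbers, and the sign convention is package-wide: negative SOA
means the probe was shown first.  Comment lines starting with ``#`` are
ignored on read and used on write to embed provenance (resolved
configuration and seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .synthetic import ExperimentDesign, JudgmentData

__all__ = ["read_judgment_csv", "write_judgment_csv", "write_json_artifact",
           "read_json_artifact", "CSV_COLUMNS"]

CSV_COLUMNS = ("participant", "condition", "soa_ms", "n_trials", "n_probe_first")


def read_judgment_csv(path) -> dict[tuple[str, str], JudgmentData]:
    """Read a judgment CSV into a ``{(participant, condition): JudgmentData}`` map.

    Row order is irrelevant; rows are sorted by SOA per cell.  Schema
    violations raise :class:`SchemaError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["soa_ms"] = df["soa_ms"].astype(float)
        df["n_trials"] = df["n_trials"].astype(int)
        df["n_probe_first"] = df["n_probe_first"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric value in a numeric column ({exc})")

    bad = df[(df.n_probe_first < 0) | (df.n_probe_first > df.n_trials) | (df.n_trials < 1)]
    if not bad.empty:
        i = bad.index[0]
        raise SchemaError(
            f"{path} row {i + 2}: n_probe_first={df.loc[i, 'n_probe_first']} "
            f"outside [0, n_trials={df.loc[i, 'n_trials']}]"
        )

    out: dict[tuple[str, str], JudgmentData] = {}
    for (participant, condition), cell in df.groupby(["participant", "condition"], sort=True):
        dup = cell["soa_ms"].duplicated()
        if dup.any():
            soa = cell.loc[dup.idxmax(), "soa_ms"]
            raise SchemaError(
                f"{path}: duplicate SOA {soa} ms for participant "
                f"{participant!r}, condition {condition!r}"
            )
        cell = cell.sort_values("soa_ms")
        design = ExperimentDesign(
            label=f"{participant}/{condition}",
            soas=tuple(cell["soa_ms"]),
            repetitions=tuple(cell["n_trials"]),
        )
        out[(str(participant), str(condition))] = JudgmentData(
            design=design, probe_first_counts=tuple(cell["n_probe_first"])
        )
    return out


def write_judgment_csv(path, datasets: dict[tuple[str, str], JudgmentData],
                       provenance: dict | None = None) -> None:
    """Write datasets to the judgment-CSV schema.

    ``provenance`` (e.g. the resolved simulation config and seed) is
    embedded as ``#``-prefixed comment lines above the header.
    """
    rows = []
    for (participant, condition), data in datasets.items():
        for soa, n, k in zip(data.design.soas, data.design.repetitions,
                             data.probe_first_counts):
            rows.append((participant, condition, soa, n, k))
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def write_json_artifact(path, payload: dict, provenance: dict | None = None) -> None:
    """Write a result JSON with its resolved configuration embedded."""
    doc = dict(payload)
    if provenance is not None:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_json_artifact(path) -> dict:
    return json.loads(Path(path).read_text())
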