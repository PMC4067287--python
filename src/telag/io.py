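"""Tabular input and JSON/TSV report serialization.

Series tables are plain delimited text (CSV/TSV), one column per variable,
header row with variable ids, integer symbols.  Reports are JSON records
carrying enough provenance (seed, estimator settings, n_effective, version)
to re-run the command, and round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .infomeasures import DiscreteSeries, LagScan, TEResult, bin_continuous

__all__ = [
    "read_series_table",
    "write_series_table",
    "write_te_report",
    "read_te_report",
    "write_lag_scan_tsv",
]


def read_series_table(
    path: str | Path, bins: int | None = None, alphabet_size: int | None = None
) -> dict[str, DiscreteSeries]:
    """Parse a delimited table into named discrete series.

    Columns must be integer-valued unless ``bins`` is given, in which case
    each column is equal-width binned into ``bins`` symbols.  The alphabet
    is inferred per table (max symbol + 1) unless ``alphabet_size`` is set.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    # csv sniffing breaks on single-column files; pick the delimiter directly
    sep = "\t" if "\t" in header else ";" if ";" in header else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise ValueError("no data rows")
    out: dict[str, DiscreteSeries] = {}
    if bins is not None:
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
            out[str(col)] = bin_continuous(vals, bins)
        return out
    M = alphabet_size
    if M is None:
        M = 0
        for col in df.columns:
            v = df[col].to_numpy()
            if not np.issubdtype(v.dtype, np.integer):
                raise ValueError(
                    f"column {col!r} is not integer-valued; pass bins= to discretize"
                )
            M = max(M, int(v.max()) + 1)
        M = max(M, 2)
    for col in df.columns:
        out[str(col)] = DiscreteSeries(df[col].to_numpy(dtype=np.int64), M)
    return out


def write_series_table(
    series: dict[str, DiscreteSeries] | dict[str, np.ndarray],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write named series as a delimited table (header row, one row per step)."""
    cols = {
        name: (s.values if isinstance(s, DiscreteSeries) else np.asarray(s))
        for name, s in series.items()
    }
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def _record(res: TEResult, source: str, target: str, seed: int | None) -> dict:
    return {
        "source": source,
        "target": target,
        "lag": res.lag,
        "te_bits": res.value,
        "n_effective": res.n_effective,
        "estimator": res.estimator,
        "seed": seed,
        "version": __version__,
    }


def write_te_report(
    results: Sequence[TEResult] | LagScan,
    path: str | Path,
    source: str = "source",
    target: str = "target",
    seed: int | None = None,
) -> None:
    """Write TE results as a JSON list of records, sorted by lag."""
    if isinstance(results, LagScan):
        results = results.results
    records = sorted(
        (_record(r, source, target, seed) for r in results), key=lambda r: r["lag"]
    )
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_te_report(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_lag_scan_tsv(scan: LagScan, path: str | Path) -> None:
    """Wide TSV of a lag scan: one row per lag with value and n_effective."""
    df = pd.DataFrame(
        {
            "lag": [r.lag for r in scan.results],
            "te_bits": [r.value for r in scan.results],
            "n_effective": [r.n_effective for r in scan.results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
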