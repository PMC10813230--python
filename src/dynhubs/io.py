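"""TSV-based persistence for cohorts and stage outputs.

All inter-stage files are plain UTF-8 TSV with '.' decimal separators:

* subject file — T rows x N columns, header row of region names;
* region table — columns region_index, region_name, rsn;
* manifest — columns subject_id, group, file, seed;
* ground truth — flat key-value text (`hubs.state_<k>` and
  `state_seq.<subject_id>` entries).

Floats are written with 17 significant digits so a write -> read round
trip is bit-exact.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .regions import RegionTable
from .synthetic import Cohort, ParcellatedTimeSeries

FLOAT_FMT = "%.17g"


def save_timeseries(ts: ParcellatedTimeSeries, path) -> None:
    """Write one subject matrix as TSV with a region-name header row."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(ts.region_table.region_name) + "\n")
        np.savetxt(fh, ts.data, fmt=FLOAT_FMT, delimiter="\t")


def load_timeseries(
    path, region_table_path, *, subject_id: str | None = None, group: str = "NC"
) -> ParcellatedTimeSeries:
    """Read and validate one subject matrix against a region table.

    Header names must match the region table's order exactly; missing or
    non-numeric cells raise :class:`ParseError` naming row and column.
    """
    path = Path(path)
    table = region_table_path if isinstance(region_table_path, RegionTable) else RegionTable.from_tsv(region_table_path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != table.region_name:
            for k, (got, want) in enumerate(zip(header, table.region_name)):
                if got != want:
                    raise ParseError(
                        f"{path}: header column {k + 1} is {got!r}, region table "
                        f"expects {want!r}"
                    )
            raise ParseError(
                f"{path}: header has {len(header)} columns, region table has "
                f"{table.n_regions}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != table.n_regions:
                raise ParseError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected "
                    f"{table.n_regions}"
                )
            row = []
            for col, cell in enumerate(cells):
                if cell.strip() == "":
                    raise ParseError(
                        f"{path}: missing value at row {lineno}, column {col + 1} "
                        f"({table.region_name[col]})"
                    )
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at row {lineno}, "
                        f"column {col + 1} ({table.region_name[col]})"
                    ) from exc
            rows.append(row)
    data = np.asarray(rows, dtype=float)
    return ParcellatedTimeSeries(
        subject_id=subject_id or path.stem,
        group=group,
        data=data,
        region_table=table,
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write subject files, region table, manifest and ground truth."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ParseError(f"output directory {out} is not writable: {exc}") from exc
    cohort.region_table.to_tsv(out / "region_table.tsv")
    rows = []
    for ts in cohort.subjects:
        fname = f"{ts.subject_id}.tsv"
        save_timeseries(ts, out / fname)
        rows.append(
            {
                "subject_id": ts.subject_id,
                "group": ts.group,
                "file": fname,
                "seed": cohort.subject_seeds[ts.subject_id],
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    with (out / "ground_truth.txt").open("w", encoding="utf-8") as fh:
        for k, hubs in enumerate(cohort.hubs_per_state):
            fh.write(f"hubs.state_{k} = {','.join(str(h) for h in hubs)}\n")
        for sid, truth in cohort.truths.items():
            seq = ",".join(str(s) for s in truth.state_sequence)
            fh.write(f"state_seq.{sid} = {seq}\n")
    return out


def load_cohort_subjects(input_dir, region_table_path=None) -> list[ParcellatedTimeSeries]:
    """Load every subject listed in a manifest directory."""
    input_dir = Path(input_dir)
    manifest = input_dir / "manifest.tsv"
    if not manifest.exists():
        raise ParseError(f"no manifest.tsv in {input_dir}")
    table_path = Path(region_table_path) if region_table_path else input_dir / "region_table.tsv"
    table = RegionTable.from_tsv(table_path)
    df = pd.read_csv(manifest, sep="\t")
    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            load_timeseries(
                input_dir / row["file"],
                table,
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
            )
        )
    return subjects


def write_matrix_tsv(path, matrix, row_labels=None, col_labels=None, fmt=FLOAT_FMT) -> None:
    """Generic labelled-matrix TSV writer used by the pipeline outputs."""
    matrix = np.asarray(matrix)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if col_labels is not None:
            writer.writerow(([""] if row_labels is not None else []) + list(col_labels))
        for i, row in enumerate(matrix):
            cells = [fmt % v if isinstance(v, (float, np.floating)) else str(v) for v in row]
            if row_labels is not None:
                cells = [str(row_labels[i])] + cells
            writer.writerow(cells)
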