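"""TSV readers/writers for marker panels, genotype tables and haplotype libraries.

All tabular formats are plain tab-separated text:

* panel: columns ``name  chromosome  position_bp  assay_type  paired_with``;
  ``paired_with`` is "." for SSRs and ``"<empty_col>,<full_col>"`` for an
  insertion-site pair (one row per logical locus).
* genotype table: leading ``#key=value`` metadata lines, then a header of
  ``sample_id  tissue`` followed by one column per assay.  SSR cells hold
  allele labels joined by the declared delimiter (``#delimiter=/`` by
  default; "-" is always accepted as a separator as well), an empty cell is
  an observed amplification failure, and "." marks a locus not assayed.
  Insertion-site assay columns hold 1/0 presence codes.
* haplotype library: header ``marker`` then one column per haplotype name;
  entries are allele labels, ``NULL`` for a deleted state and ``?`` for an
  unresolved one.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .model import (
    NULL,
    UNKNOWN,
    AlleleCall,
    AssayType,
    EMPTY_SITE,
    FULL_SITE,
    GenotypeTable,
    Haplotype,
    MISSING_CALL,
    MarkerDef,
    MarkerPanel,
    SampleGenotype,
    Tissue,
)

__all__ = [
    "read_panel",
    "write_panel",
    "read_genotype_table",
    "write_genotype_table",
    "read_haplotype_library",
    "write_haplotype_library",
]

_MISSING_TOKEN = "."


def read_panel(path: str | Path) -> MarkerPanel:
    markers: list[MarkerDef] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            assay_type = AssayType(row["assay_type"])
            paired = row.get("paired_with", _MISSING_TOKEN).strip()
            paired_assays = None
            if assay_type is AssayType.INSERTION_SITE_PAIR:
                parts = [p.strip() for p in paired.split(",")]
                if len(parts) != 2:
                    raise ValueError(
                        f"insertion pair {row['name']!r} needs 'empty,full' assay columns, got {paired!r}"
                    )
                paired_assays = (parts[0], parts[1])
            markers.append(
                MarkerDef(
                    name=row["name"],
                    chromosome=row["chromosome"],
                    position_bp=int(row["position_bp"]),
                    assay_type=assay_type,
                    paired_assays=paired_assays,
                )
            )
    return MarkerPanel(markers)


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "chromosome", "position_bp", "assay_type", "paired_with"])
        for m in panel:
            paired = ",".join(m.paired_assays) if m.paired_assays else _MISSING_TOKEN
            w.writerow([m.name, m.chromosome, m.position_bp, m.assay_type.value, paired])


def _split_labels(cell: str, delimiter: str) -> list[str]:
    cell = cell.replace("-", delimiter) if delimiter != "-" else cell
    return [p for p in (x.strip() for x in cell.split(delimiter)) if p]


def _parse_ssr_cell(cell: str, delimiter: str, where: str) -> AlleleCall:
    cell = cell.strip()
    if cell == _MISSING_TOKEN:
        return MISSING_CALL
    if not cell:
        return AlleleCall.of()
    labels = _split_labels(cell, delimiter)
    for lab in labels:
        if not lab.isdigit():
            raise ValueError(f"non-numeric SSR allele label {lab!r} at {where}")
    return AlleleCall.of(*labels)


def _parse_presence(cell: str, where: str) -> bool | None:
    """1/0 insertion-assay code; None = not assayed."""
    cell = cell.strip()
    if cell == _MISSING_TOKEN:
        return None
    if cell in ("", "0"):
        return False
    if cell == "1":
        return True
    raise ValueError(f"insertion-site assay expects 1/0 at {where}, got {cell!r}")


def read_genotype_table(path: str | Path, panel: MarkerPanel) -> GenotypeTable:
    metadata: dict[str, str] = {}
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            metadata[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    delimiter = metadata.get("delimiter", "/")
    if not body:
        raise ValueError(f"{path}: empty genotype table")
    rows = list(csv.reader(body, delimiter="\t"))
    header = [h.strip() for h in rows[0]]
    if header[:2] != ["sample_id", "tissue"]:
        raise ValueError(f"{path}: header must start with sample_id, tissue")

    known_columns: dict[str, tuple[MarkerDef, str | None]] = {}
    for m in panel:
        if m.assay_type is AssayType.INSERTION_SITE_PAIR:
            empty_col, full_col = m.paired_assays  # type: ignore[misc]
            known_columns[empty_col] = (m, EMPTY_SITE)
            known_columns[full_col] = (m, FULL_SITE)
        else:
            known_columns[m.name] = (m, None)
    for col in header[2:]:
        if col not in known_columns:
            raise ValueError(f"{path}: unknown marker column {col!r}")

    col_index = {col: i for i, col in enumerate(header)}
    samples: list[SampleGenotype] = []
    for r, row in enumerate(rows[1:], start=2):
        sample_id, tissue = row[0].strip(), Tissue(row[1].strip())
        calls: dict[str, AlleleCall] = {}
        for m in panel:
            if m.assay_type is AssayType.INSERTION_SITE_PAIR:
                empty_col, full_col = m.paired_assays  # type: ignore[misc]
                states: dict[str, bool | None] = {}
                for col, label in ((empty_col, EMPTY_SITE), (full_col, FULL_SITE)):
                    if col not in col_index:
                        states[label] = None
                        continue
                    states[label] = _parse_presence(
                        row[col_index[col]], f"row {r}, column {col!r}"
                    )
                if None in states.values():
                    # partial amplification data for the pair: treated as
                    # missing for the whole logical locus
                    calls[m.name] = MISSING_CALL
                else:
                    present = [lab for lab, on in states.items() if on]
                    calls[m.name] = AlleleCall.of(*present)
            else:
                if m.name not in col_index:
                    calls[m.name] = MISSING_CALL
                    continue
                calls[m.name] = _parse_ssr_cell(
                    row[col_index[m.name]], delimiter, f"row {r}, column {m.name!r}"
                )
        samples.append(SampleGenotype(sample_id, tissue, calls))
    return GenotypeTable(panel=panel, samples=samples, metadata=metadata)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    panel = table.panel
    delimiter = table.metadata.get("delimiter", "/")
    columns: list[str] = []
    for m in panel:
        columns.extend(m.assay_columns)
    with open(path, "w", newline="") as fh:
        for key, value in sorted(table.metadata.items()):
            fh.write(f"#{key}={value}\n")
        if "delimiter" not in table.metadata:
            fh.write(f"#delimiter={delimiter}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "tissue"] + columns)
        for s in table.samples:
            row: list[str] = [s.sample_id, s.tissue.value]
            for m in panel:
                call = s.call(m.name)
                if m.assay_type is AssayType.INSERTION_SITE_PAIR:
                    if call.missing:
                        row.extend([_MISSING_TOKEN, _MISSING_TOKEN])
                    else:
                        row.append("1" if EMPTY_SITE in call.alleles else "0")
                        row.append("1" if FULL_SITE in call.alleles else "0")
                else:
                    if call.missing:
                        row.append(_MISSING_TOKEN)
                    else:
                        row.append(delimiter.join(sorted(call.alleles, key=_label_key)))
            w.writerow(row)


def _label_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


_NULL_TOKEN = "NULL"
_UNKNOWN_TOKEN = "?"


def read_haplotype_library(path: str | Path, panel: MarkerPanel) -> list[Haplotype]:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row and not row[0].startswith("#")]
    header = [h.strip() for h in rows[0]]
    if header[0] != "marker":
        raise ValueError(f"{path}: first column of a haplotype library must be 'marker'")
    names = header[1:]
    alleles: dict[str, dict] = {name: {} for name in names}
    for row in rows[1:]:
        marker = row[0].strip()
        if marker not in panel:
            raise ValueError(f"{path}: unknown marker {marker!r}")
        for name, cell in zip(names, (c.strip() for c in row[1:])):
            if cell == _NULL_TOKEN:
                alleles[name][marker] = NULL
            elif cell in (_UNKNOWN_TOKEN, ""):
                alleles[name][marker] = UNKNOWN
            else:
                alleles[name][marker] = cell
    return [Haplotype(name, alleles[name]) for name in names]


def write_haplotype_library(haplotypes: list[Haplotype], panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker"] + [h.name for h in haplotypes])
        for m in panel:
            row = [m.name]
            for h in haplotypes:
                state = h[m.name]
                if state is NULL:
                    row.append(_NULL_TOKEN)
                elif state is UNKNOWN:
                    row.append(_UNKNOWN_TOKEN)
                else:
                    row.append(str(state))
            w.writerow(row)
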