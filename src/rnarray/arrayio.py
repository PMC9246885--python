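"""Readers and writers for every external format the toolkit touches.

All text dialects are tab-separated, UTF-8, "\n"-terminated, with fixed
column order and numbers formatted to 6 significant digits, so writers are
byte-deterministic. GenePix coordinates are 1-based: Block = 1,
Column = col + 1, Row = row + 1. Only the documented column subsets are
required on read; extra columns pass through untouched.

FASTA goes through Biopython, raster images (PPM P6 / PNG) and mask bitmaps
(PBM) through Pillow, config files through PyYAML.
"""

from __future__ import annotations

import io
import os
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import DesignTable, TemplateSpec
from .imagecode import ArrayLayout
from .lithoplan import Cycle, MONOMER_SPECS, SynthesisPlan
from .scansim import ScanTable
from .seqcore import ChimericOligo

__all__ = [
    "ParseError",
    "DialectError",
    "read_fasta",
    "write_fasta",
    "read_design_tsv",
    "write_design_tsv",
    "read_chimera_tsv",
    "write_chimera_tsv",
    "read_gal",
    "write_gal",
    "read_gpr",
    "write_gpr",
    "read_scan_tsv",
    "write_scan_tsv",
    "read_image",
    "write_ppm",
    "read_mask",
    "write_mask",
    "write_plan",
    "read_plan",
    "read_config",
    "write_config",
]


class ParseError(ValueError):
    """A file violates its dialect; the message names line and column."""


class DialectError(ParseError):
    """Unsupported format/version tag."""


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return "" if x is None else str(x)


# ---------------------------------------------------------------- FASTA ----

def write_fasta(records: Mapping[str, str] | Iterable[Tuple[str, str]], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    items = records.items() if isinstance(records, Mapping) else records
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------- design TSV ----

_DESIGN_COLUMNS = [
    "probe_id",
    "role",
    "linker_len",
    "variable",
    "full_sequence",
    "primer_name",
    "primer_block",
    "channel",
    "level",
    "ru_position",
    "response_len",
]


def write_design_tsv(design: DesignTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# replicate_count\t{design.replicate_count}\n")
        for key in sorted(design.metadata):
            fh.write(f"# {key}\t{design.metadata[key]}\n")
        fh.write("\t".join(_DESIGN_COLUMNS) + "\n")
        for t in design:
            row = [
                t.probe_id,
                t.role,
                str(t.linker_len),
                t.variable,
                t.full_sequence,
                t.primer_name,
                t.primer_block,
                _fmt(t.channel),
                _fmt(t.level),
                _fmt(t.ru_position),
                _fmt(t.response_len),
            ]
            fh.write("\t".join(row) + "\n")


def read_design_tsv(path) -> DesignTable:
    replicate_count = 1
    metadata: Dict[str, object] = {}
    templates: List[TemplateSpec] = []
    with open(path, encoding="utf-8") as fh:
        header: Optional[List[str]] = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                if key == "replicate_count":
                    replicate_count = int(val)
                else:
                    metadata[key] = val
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _DESIGN_COLUMNS[:5] if c not in header]
                if missing:
                    raise ParseError(f"line {lineno}: missing column(s) {missing}")
                continue
            rec = dict(zip(header, fields))
            templates.append(
                TemplateSpec(
                    probe_id=rec["probe_id"],
                    variable=rec["variable"],
                    linker_len=int(rec["linker_len"]),
                    role=rec["role"],
                    primer_name=rec.get("primer_name", "P15"),
                    primer_block=rec.get("primer_block", ""),
                    channel=rec.get("channel") or None,
                    level=int(rec["level"]) if rec.get("level") else None,
                    ru_position=int(rec["ru_position"]) if rec.get("ru_position") else None,
                    response_len=int(rec["response_len"]) if rec.get("response_len") else None,
                )
            )
    return DesignTable(templates, replicate_count=replicate_count, metadata=metadata)


# ---------------------------------------------------------- chimera TSV ----

def write_chimera_tsv(records: Mapping[str, ChimericOligo], path) -> None:
    """Chimera dialect: name, label5, label3, segments as chem:seq joined by '|'."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("name\tlabel5\tlabel3\tsegments\n")
        for name in records:
            o = records[name]
            fh.write(f"{name}\t{o.label5.value}\t{o.label3.value}\t{o.to_fields()}\n")


def read_chimera_tsv(path) -> Dict[str, ChimericOligo]:
    out: Dict[str, ChimericOligo] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("name", "label5", "segments"):
            if col not in header:
                raise ParseError(f"line 1: missing column {col!r}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            rec = dict(zip(header, line.split("\t")))
            out[rec["name"]] = ChimericOligo.from_fields(
                rec["segments"], rec.get("label5", "none"), rec.get("label3", "none")
            )
    return out


# ------------------------------------------------------------- ATF core ----

def _write_atf(path, file_type: str, header_records: Sequence[str], frame: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        records = [f'"Type={file_type}"'] + [f'"{h}"' for h in header_records]
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(records)}\t{len(frame.columns)}\n")
        for rec in records:
            fh.write(rec + "\n")
        fh.write("\t".join(f'"{c}"' for c in frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _read_atf(path) -> Tuple[str, List[str], pd.DataFrame]:
    with open(path, encoding="utf-8") as fh:
        magic = fh.readline().rstrip("\n").split("\t")
        if len(magic) != 2 or magic[0] != "ATF":
            raise DialectError("line 1: not an ATF file")
        if magic[1] != "1.0":
            raise DialectError(f"line 1: unsupported ATF version {magic[1]!r}")
        counts = fh.readline().rstrip("\n").split("\t")
        try:
            n_records = int(counts[0])
        except (ValueError, IndexError):
            raise ParseError("line 2: malformed record/column counts")
        headers = []
        for i in range(n_records):
            headers.append(fh.readline().rstrip("\n").strip('"'))
        file_type = ""
        extra = []
        for h in headers:
            if h.startswith("Type="):
                file_type = h[5:]
            else:
                extra.append(h)
        cols = [c.strip('"') for c in fh.readline().rstrip("\n").split("\t")]
        rows = []
        for lineno, raw in enumerate(fh, 4 + n_records):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"line {lineno}: {len(fields)} fields, expected {len(cols)}"
                )
            rows.append(fields)
        frame = pd.DataFrame(rows, columns=cols)
        return file_type, extra, frame


def _require(cols: Sequence[str], frame: pd.DataFrame, what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ParseError(f"{what}: missing required column(s) {missing}")


# --------------------------------------------------------------- GAL -------

def write_gal(layout: ArrayLayout, design: Optional[DesignTable], path) -> None:
    """GenePix Array List: Block/Column/Row/Name/ID, 1-based coordinates."""
    rows = []
    for (r, c), pid in sorted(layout.features.items()):
        rows.append({"Block": 1, "Column": c + 1, "Row": r + 1, "Name": pid, "ID": pid})
    frame = pd.DataFrame(rows, columns=["Block", "Column", "Row", "Name", "ID"])
    headers = [f"BlockCount=1", f"GridRows={layout.n_rows}", f"GridCols={layout.n_cols}"]
    _write_atf(path, "GenePix ArrayList V1.0", headers, frame)


def read_gal(path) -> ArrayLayout:
    file_type, headers, frame = _read_atf(path)
    if "ArrayList" not in file_type:
        raise DialectError(f"not a GAL file (Type={file_type!r})")
    _require(["Block", "Column", "Row", "Name", "ID"], frame, "GAL")
    meta = dict(h.split("=", 1) for h in headers if "=" in h)
    n_rows = int(meta["GridRows"]) if "GridRows" in meta else None
    n_cols = int(meta["GridCols"]) if "GridCols" in meta else None
    features = {
        (int(rec.Row) - 1, int(rec.Column) - 1): rec.ID
        for rec in frame.itertuples(index=False)
    }
    if n_rows is None:
        n_rows = max((r for r, _ in features), default=-1) + 1
    if n_cols is None:
        n_cols = max((c for _, c in features), default=-1) + 1
    return ArrayLayout(n_rows, n_cols, features)


# --------------------------------------------------------------- GPR -------

def write_gpr(scan: ScanTable, path) -> None:
    """GPR subset: Block/Column/Row/Name/ID plus 'F<l> Median'/'B<l> Median'
    per scanned wavelength."""
    frame = scan.frame
    channels = sorted(frame["channel"].unique())
    wide = None
    for ch in channels:
        sub = frame[frame["channel"] == ch][["row", "col", "probe_id", "F", "B"]]
        sub = sub.rename(columns={"F": f"F{ch} Median", "B": f"B{ch} Median"})
        wide = sub if wide is None else wide.merge(sub, on=["row", "col", "probe_id"])
    wide = wide.sort_values(["row", "col"]).reset_index(drop=True)
    out = pd.DataFrame(
        {
            "Block": 1,
            "Column": wide["col"] + 1,
            "Row": wide["row"] + 1,
            "Name": wide["probe_id"],
            "ID": wide["probe_id"],
        }
    )
    for ch in channels:
        out[f"F{ch} Median"] = wide[f"F{ch} Median"]
        out[f"B{ch} Median"] = wide[f"B{ch} Median"]
    _write_atf(path, "GenePix Results V1.0", [], out)


def read_gpr(path) -> ScanTable:
    file_type, _, frame = _read_atf(path)
    if "Results" not in file_type:
        raise DialectError(f"not a GPR file (Type={file_type!r})")
    _require(["Block", "Column", "Row", "Name", "ID"], frame, "GPR")
    f_cols = [c for c in frame.columns if c.startswith("F") and c.endswith(" Median")]
    if not f_cols:
        raise ParseError("GPR: no 'F<wavelength> Median' column found")
    long_rows = []
    records = frame.to_dict("records")
    for col in f_cols:
        ch = int(col[1:-7])
        bcol = f"B{ch} Median"
        for rd in records:
            long_rows.append(
                {
                    "row": int(rd["Row"]) - 1,
                    "col": int(rd["Column"]) - 1,
                    "probe_id": rd["ID"],
                    "channel": ch,
                    "F": float(rd[col]),
                    "B": float(rd[bcol]) if bcol in rd else 0.0,
                }
            )
    return ScanTable(pd.DataFrame(long_rows, columns=["row", "col", "probe_id", "channel", "F", "B"]))


# ----------------------------------------------------------- scan TSV ------

_SCAN_COLUMNS = ["row", "col", "probe_id", "channel", "F", "B"]


def write_scan_tsv(scan: ScanTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SCAN_COLUMNS) + "\n")
        for rec in scan.frame[_SCAN_COLUMNS].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in rec) + "\n")


def read_scan_tsv(path) -> ScanTable:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _SCAN_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"scan TSV: missing column(s) {missing}")
    return ScanTable(frame[_SCAN_COLUMNS])


# ------------------------------------------------------------- images ------

def read_image(path) -> np.ndarray:
    """Read a P6 PPM or PNG into an (H, W, 3) uint8 raster."""
    from PIL import Image

    with Image.open(path) as im:
        if im.mode != "RGB":
            im = im.convert("RGB")
        return np.asarray(im).copy()


def write_ppm(raster: np.ndarray, path) -> None:
    """Write an (H, W, 3) uint8 raster as binary (P6) PPM."""
    from PIL import Image

    arr = np.asarray(raster, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ParseError(f"expected (H, W, 3) raster, got {arr.shape}")
    Image.fromarray(arr, "RGB").save(str(path), format="PPM")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mirror mask as a portable bitmap (ON = white)."""
    from PIL import Image

    arr = np.asarray(mask, dtype=bool)
    Image.fromarray(arr.astype(np.uint8) * 255, "L").convert("1").save(
        str(path), format="PPM"
    )


def read_mask(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("1"), dtype=bool).copy()


# ------------------------------------------------------ synthesis plan -----

def write_plan(plan: SynthesisPlan, out_dir) -> Path:
    """Write the cycle manifest plus one PBM mask per masked cycle.

    Returns the manifest path. Manifest columns: cycle index, monomer, mask
    file name (or FLOOD), dose (J/cm2), coupling_time (s).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "cycles.tsv"
    with open(manifest, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cycle\tmonomer\tmask\tdose\tcoupling_time\n")
        for i, cyc in enumerate(plan.cycles):
            if cyc.is_flood:
                mask_field = "FLOOD"
            else:
                mask_field = f"{cyc.mask_id}.pbm"
                write_mask(plan.masks[cyc.mask_id], out / mask_field)
            fh.write(
                f"{i}\t{cyc.monomer}\t{mask_field}\t{_fmt(cyc.dose)}\t{_fmt(cyc.coupling_time)}\n"
            )
    return manifest


def read_plan(manifest_path, grid: Optional[Tuple[int, int]] = None) -> SynthesisPlan:
    manifest_path = Path(manifest_path)
    cycles: List[Cycle] = []
    masks: Dict[str, np.ndarray] = {}
    with open(manifest_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("cycle", "monomer", "mask", "dose", "coupling_time"):
            if col not in header:
                raise ParseError(f"manifest line 1: missing column {col!r}")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            rec = dict(zip(header, line.split("\t")))
            if rec["mask"] == "FLOOD":
                mask_id = None
            else:
                mask_id = rec["mask"].removesuffix(".pbm")
                masks[mask_id] = read_mask(manifest_path.parent / rec["mask"])
            cycles.append(
                Cycle(rec["monomer"], mask_id, float(rec["dose"]), float(rec["coupling_time"]))
            )
    if grid is None:
        grid = next(iter(masks.values())).shape if masks else (0, 0)
    return SynthesisPlan(cycles, masks, tuple(grid))


# -------------------------------------------------------------- config -----

def read_config(path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_config(config: Mapping, path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
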