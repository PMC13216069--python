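"""Readers and writers for interchange formats, Tn5 offset correction, config.

All genomic coordinates throughout the package are 0-based half-open.
Formats handled here:

* BED3/BED6+ intervals (peaks, motif instances, annotations);
* the motif block text format: per block a header
  ``>label polarity=+|- n_seqlets=<int> kind=CWM|PPM`` followed by L rows of
  4 whitespace-separated numbers in A,C,G,T order, blank line between blocks;
* MEME minimal format for PPMs (read via Bio.motifs; written directly since
  biopython has no minimal-format writer);
* fragment TSV (chrom, start, end, barcode, count) and effect-table TSVs;
* the +4/-4 (consensus) and legacy +4/-5 Tn5 insertion offset schemes with a
  mate-consistency checker.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .instances import MotifInstance
from .motifs import Motif
from .synthetic import TN5_HALF_SPAN, FragmentRecord

__all__ = [
    "read_bed",
    "write_bed",
    "instances_to_bed",
    "bed_to_instances",
    "read_motifs",
    "write_motifs",
    "read_meme",
    "write_meme",
    "read_fragments",
    "write_fragments",
    "TN5_SCHEMES",
    "tn5_offset_correct",
    "mate_consistency_check",
    "RunConfig",
    "load_config",
]

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    pass


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6+ into a DataFrame, validating each line.

    Malformed rows (missing columns, non-integer or negative coordinates,
    start >= end) raise :class:`BedParseError` naming the 1-based line
    number.  Output is sorted by (chrom, start, end).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from None
            if start < 0:
                raise BedParseError(f"line {lineno}: negative coordinate")
            if start >= end:
                raise BedParseError(f"line {lineno}: start >= end")
            rows.append([parts[0], start, end] + parts[3:])
    if not rows:
        return pd.DataFrame(columns=_BED_COLUMNS[:3])
    width = max(len(r) for r in rows)
    cols = _BED_COLUMNS[:width] + [f"col{i}" for i in range(7, width + 1)]
    df = pd.DataFrame([r + [""] * (width - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write intervals as BED, sorted by (chrom, start, end)."""
    out = df.sort_values(["chrom", "start", "end"])
    out.to_csv(path, sep="\t", header=False, index=False)


def instances_to_bed(instances: Iterable[MotifInstance], path) -> None:
    """Write motif instances as BED6+2 (name=label, score=1000 x correlation
    clamped to [0, 1000], extra columns hit_correlation and contribution)."""
    rows = [
        {
            "chrom": i.chrom,
            "start": i.start,
            "end": i.end,
            "name": i.label,
            "score": int(np.clip(round(1000 * i.hit_correlation), 0, 1000)),
            "strand": i.strand,
            "hit_correlation": f"{i.hit_correlation:.6f}",
            "contribution": f"{i.contribution:.6f}",
        }
        for i in instances
    ]
    write_bed(pd.DataFrame(rows), path)


def bed_to_instances(path) -> list[MotifInstance]:
    df = read_bed(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            MotifInstance(
                chrom=r["chrom"],
                start=int(r["start"]),
                end=int(r["end"]),
                strand=r.get("strand", "+") or "+",
                label=r.get("name", "motif"),
                hit_correlation=float(r.get("col7", r.get("score", 0)) or 0),
                contribution=float(r.get("col8", 0) or 0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# motif block format

def write_motifs(motifs: Iterable[Motif], path) -> None:
    """Write motifs in the block text format (a CWM and a PPM block each)."""
    with open(path, "w") as fh:
        for m in motifs:
            sign = "+" if m.polarity == "positive" else "-"
            for kind, mat in (("CWM", m.cwm), ("PPM", m.ppm)):
                fh.write(f">{m.label} polarity={sign} n_seqlets={m.n_seqlets} kind={kind}\n")
                for col in mat.T:
                    fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
                fh.write("\n")


def _parse_header(line: str, lineno: int) -> dict:
    if not line.startswith(">"):
        raise ValueError(f"line {lineno}: expected motif header starting with '>'")
    fields = line[1:].split()
    if not fields:
        raise ValueError(f"line {lineno}: empty motif header")
    meta = {"label": fields[0], "n_seqlets": None, "polarity": "+", "kind": "CWM"}
    for item in fields[1:]:
        if "=" not in item:
            raise ValueError(f"line {lineno}: malformed header field {item!r}")
        k, v = item.split("=", 1)
        meta[k] = v
    return meta


def read_motifs(path, ppm_tol: float = 1e-3) -> list[Motif]:
    """Read the block text format, pairing CWM and PPM blocks by label.

    Rows must have exactly 4 columns; PPM columns must sum to 1 within
    ``ppm_tol``.  A CWM block without ``n_seqlets`` defaults to 0 with a
    warning.  A label with only one block kind gets a uniform PPM (CWM-only)
    or a zero CWM (PPM-only).
    """
    import warnings

    blocks: dict[tuple, np.ndarray] = {}
    meta_by_label: dict[str, dict] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        meta = _parse_header(lines[i], i + 1)
        i += 1
        rows = []
        while i < len(lines) and lines[i].strip() and not lines[i].startswith(">"):
            parts = lines[i].split()
            if len(parts) != 4:
                raise ValueError(
                    f"motif {meta['label']!r}: row with {len(parts)} columns (need 4)"
                )
            rows.append([float(x) for x in parts])
            i += 1
        mat = np.array(rows).T  # rows are positions in the file; matrix is 4 x L
        if meta["kind"] == "PPM":
            colsums = mat.sum(axis=0)
            if np.any(np.abs(colsums - 1) > ppm_tol):
                raise ValueError(f"motif {meta['label']!r}: PPM columns do not sum to 1")
        if meta["n_seqlets"] is None:
            warnings.warn(f"motif {meta['label']!r}: n_seqlets missing, defaulting to 0")
            meta["n_seqlets"] = 0
        blocks[(meta["label"], meta["kind"])] = mat
        meta_by_label.setdefault(meta["label"], meta)
    motifs = []
    for label, meta in meta_by_label.items():
        cwm = blocks.get((label, "CWM"))
        ppm = blocks.get((label, "PPM"))
        if cwm is None and ppm is None:
            continue
        if ppm is None:
            ppm = np.full_like(cwm, 0.25)
        if cwm is None:
            cwm = np.zeros_like(ppm) + 1e-9
        # renormalize the PPM against accumulated rounding
        ppm = ppm / ppm.sum(axis=0, keepdims=True)
        motifs.append(
            Motif(
                label=label,
                cwm=cwm,
                ppm=ppm,
                polarity="negative" if meta["polarity"] == "-" else "positive",
                n_seqlets=int(meta["n_seqlets"]),
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# MEME minimal format (PPMs)

def write_meme(motifs: Iterable[Motif], path) -> None:
    """Write PPMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.label}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.ppm.shape[1]} "
                f"nsites= {max(m.n_seqlets, 1)} E= 0\n"
            )
            for col in m.ppm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[Motif]:
    """Read PPMs from MEME minimal format (via Bio.motifs); CWMs are zero."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    out = []
    for m in record:
        ppm = np.array([m.pwm[b] for b in "ACGT"])
        ppm = ppm / ppm.sum(axis=0, keepdims=True)
        out.append(
            Motif(
                label=m.name,
                cwm=np.zeros_like(ppm) + 1e-9,
                ppm=ppm,
                n_seqlets=int(getattr(m, "num_occurrences", 0) or 0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# fragments + Tn5 offsets

_FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def write_fragments(fragments: Iterable[FragmentRecord], path) -> None:
    df = pd.DataFrame(
        [(f.chrom, f.start, f.end, f.barcode, f.count) for f in fragments],
        columns=_FRAGMENT_COLUMNS,
    )
    df.sort_values(["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments(path) -> list[FragmentRecord]:
    out = []
    df = pd.read_csv(path, sep="\t", header=None, names=_FRAGMENT_COLUMNS)
    for _, r in df.iterrows():
        out.append(
            FragmentRecord(
                chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
                barcode=str(r["barcode"]),
                count=1 if pd.isna(r["count"]) else int(r["count"]),
            )
        )
    return out


#: offset applied to (plus-strand insertion, minus-strand insertion)
TN5_SCHEMES = {"+4/-4": (4, -4), "+4/-5": (4, -5)}


def tn5_offset_correct(
    fragments: Iterable[FragmentRecord], scheme: str = "+4/-4"
) -> pd.DataFrame:
    """Adjusted insertion records, one per fragment endpoint.

    The plus-strand insertion of a fragment is its ``start``; the
    minus-strand insertion is ``end - 1`` (the first duplicated base on the
    minus strand under the end-exclusive convention).  The +4/-4 scheme maps
    both mates of a shared transposition event to the same consensus
    coordinate; the legacy +4/-5 scheme leaves a 1-bp mismatch.
    """
    if scheme not in TN5_SCHEMES:
        raise ValueError(
            f"unknown Tn5 offset scheme {scheme!r}; supported: {sorted(TN5_SCHEMES)}"
        )
    plus_off, minus_off = TN5_SCHEMES[scheme]
    rows = []
    for f in fragments:
        rows.append((f.chrom, f.start + plus_off, "+", f.barcode))
        rows.append((f.chrom, (f.end - 1) + minus_off, "-", f.barcode))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "barcode"])


def mate_consistency_check(
    fragments: Sequence[FragmentRecord], scheme: str = "+4/-4"
) -> np.ndarray:
    """Per shared transposition event, the absolute difference between the
    adjusted insertion coordinates of the two fragments sharing it.

    Consecutive fragments within a (chrom, barcode) group share the event
    between them: the left fragment reports its minus-strand insertion and
    the right fragment its plus-strand insertion at that event.
    """
    if scheme not in TN5_SCHEMES:
        raise ValueError(
            f"unknown Tn5 offset scheme {scheme!r}; supported: {sorted(TN5_SCHEMES)}"
        )
    plus_off, minus_off = TN5_SCHEMES[scheme]
    groups: dict[tuple, list[FragmentRecord]] = {}
    for f in fragments:
        groups.setdefault((f.chrom, f.barcode), []).append(f)
    diffs = []
    for frags in groups.values():
        frags = sorted(frags, key=lambda f: f.start)
        for left, right in zip(frags, frags[1:]):
            minus_adj = (left.end - 1) + minus_off
            plus_adj = right.start + plus_off
            diffs.append(abs(plus_adj - minus_adj))
    return np.asarray(diffs, dtype=int)


# ---------------------------------------------------------------------------
# effect / synergy tables

def write_effect_table(table: pd.DataFrame, path) -> None:
    """Write a marginalization effect table as TSV (fixed column order)."""
    from .marginalize import EFFECT_COLUMNS

    table[EFFECT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_effect_table(path) -> pd.DataFrame:
    from .marginalize import EFFECT_COLUMNS

    table = pd.read_csv(path, sep="\t")
    missing = set(EFFECT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    return table


def write_synergy_calls(calls, path) -> None:
    """Write SynergyCall records as TSV."""
    rows = [
        {
            "composite_id": c.composite_id,
            "context": c.context,
            "orientation": c.orientation,
            "gap": c.gap,
            "center_distance": c.center_distance,
            "mean_diff": c.mean_diff,
            "p_raw": c.p_raw,
            "p_adj": c.p_adj,
            "z_max": c.z_max,
            "classes": ",".join(sorted(c.classes)),
            "status": c.status,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Run parameters shared across the pipeline stages."""

    seed: int = 0
    window_length: int = 2114
    profile_length: int = 1000
    n_folds: int = 5
    gap_min: int = 0
    gap_max: int = 200
    gap_step: int = 1
    n_backgrounds: int = 100
    alpha_adj: float = 0.001
    min_diff: float = 0.15
    z_hard: float = 4.0
    soft_range: tuple = (20, 150)
    eqtl_shuffles: int = 100_000
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @property
    def gaps(self) -> range:
        return range(self.gap_min, self.gap_max + 1, self.gap_step)


def load_config(path) -> RunConfig:
    """Load a YAML config document; unknown keys raise."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "soft_range" in data:
        data["soft_range"] = tuple(data["soft_range"])
    return RunConfig(**data)
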