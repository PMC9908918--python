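"""Readers and writers for every external representation the pipeline touches.

Landmark files use a plain-text dialect: a three-line header
(``id <specimen_id>``, ``species <species>|<side>``, ``structure <name>``)
followed by one whitespace-separated ``x y z`` triple per line, in mm.
Trees are strict rooted Newick with branch lengths on every edge.
Audiograms and scalar traits travel as headed CSV; results as TSV with
deterministic row and column order.

All parsing is strict: malformed content raises :class:`ParseError` or
:class:`ContentError` naming the offending line or node, never a silent
coercion.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

SIDES = ("left", "right")
STRUCTURES = ("cochlea_curve", "oval_window")
#: BA-S speaker-based behavioral, BA-H headphone behavioral, ABR auditory
#: brainstem response; "ABR-corrected" is produced by the audiometry module.
METHODS = ("BA-S", "BA-H", "ABR", "ABR-corrected")

ULTRAMETRIC_RTOL = 1e-6


class ParseError(ValueError):
    """Structurally malformed input (bad line, bad token)."""


class ContentError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass
class LandmarkFile:
    """One specimen's ordered 3D landmark/semilandmark point set (mm)."""

    specimen_id: str
    species: str
    side: str
    structure: str
    points: np.ndarray  # (n, 3) float, file order preserved

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.side not in SIDES:
            raise ContentError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if self.structure not in STRUCTURES:
            raise ContentError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ContentError("points must be an (n, 3) array")
        if len(self.points) < 3:
            raise ContentError(f"need >= 3 points, got {len(self.points)}")
        if not np.all(np.isfinite(self.points)):
            raise ContentError("non-finite coordinate in landmark file")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkFile):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.species == other.species
            and self.side == other.side
            and self.structure == other.structure
            and self.points.shape == other.points.shape
            and bool(np.array_equal(self.points, other.points))
        )


@dataclass
class AudiogramRecord:
    """Hearing-threshold curve of one species: (frequency kHz, dB SPL) rows."""

    species: str
    method: str
    frequencies_khz: np.ndarray
    thresholds_db: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_khz = np.asarray(self.frequencies_khz, dtype=float)
        self.thresholds_db = np.asarray(self.thresholds_db, dtype=float)
        if self.method not in METHODS:
            raise ContentError(
                f"unknown audiogram method {self.method!r}; expected one of {METHODS}"
            )
        if len(self.frequencies_khz) != len(self.thresholds_db):
            raise ContentError("frequency/threshold length mismatch")
        if len(self.frequencies_khz) < 3:
            raise ContentError("audiogram needs >= 3 rows")
        if not np.all(self.frequencies_khz > 0):
            raise ContentError("frequencies must be positive (kHz)")
        if np.any(np.diff(self.frequencies_khz) <= 0):
            raise ContentError(
                f"frequencies must be strictly increasing "
                f"(species {self.species!r})"
            )
        if not np.all(np.isfinite(self.thresholds_db)):
            raise ContentError("non-finite threshold")

    @property
    def rows(self) -> list[tuple[float, float]]:
        return list(zip(self.frequencies_khz.tolist(), self.thresholds_db.tolist()))


class Phylogeny:
    """Rooted tree with branch lengths; thin validated wrapper over dendropy.

    Branch lengths are in Myr throughout the pipeline.  ``is_ultrametric``
    is computed at construction with relative tolerance 1e-6 on the spread
    of root-to-tip depths.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ContentError(f"duplicate tip label(s): {dup}")
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise ContentError(f"missing branch length above node {name!r}")
            if node.edge.length <= 0:
                name = node.taxon.label if node.taxon else "<internal>"
                raise ContentError(f"non-positive branch length above node {name!r}")
        self.tip_labels: list[str] = sorted(labels)
        depths = self.tip_depths()
        d = np.array([depths[t] for t in self.tip_labels])
        self.is_ultrametric = bool((d.max() - d.min()) <= ULTRAMETRIC_RTOL * d.max())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> dict[str, float]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return self.as_newick() == other.as_newick()


# ---------------------------------------------------------------- landmarks


def parse_landmark_file(stream: str | io.TextIOBase) -> LandmarkFile:
    """Parse the native landmark dialect; errors cite 1-based line numbers."""
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    lines = text.splitlines()
    header: dict[str, str] = {}
    points: list[list[float]] = []
    n_header = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if n_header < 3:
            if toks[0] not in ("id", "species", "structure"):
                raise ParseError(
                    f"line {lineno}: expected header keyword, got {toks[0]!r}"
                )
            header[toks[0]] = " ".join(toks[1:])
            n_header += 1
            continue
        if len(toks) != 3:
            raise ParseError(f"line {lineno}: expected 3 coordinates, got {len(toks)}")
        try:
            points.append([float(t) for t in toks])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric coordinate in {line!r}")
    missing = {"id", "species", "structure"} - set(header)
    if missing:
        raise ParseError(f"missing header field(s): {sorted(missing)}")
    if len(points) < 3:
        raise ContentError(f"need >= 3 points, got {len(points)}")
    species, _, side = header["species"].rpartition("|")
    if not species:
        raise ParseError("species header must be '<species>|<side>'")
    return LandmarkFile(
        specimen_id=header["id"],
        species=species,
        side=side,
        structure=header["structure"],
        points=np.array(points, dtype=float),
    )


def write_landmark_file(lm: LandmarkFile) -> str:
    out = [
        f"id {lm.specimen_id}",
        f"species {lm.species}|{lm.side}",
        f"structure {lm.structure}",
    ]
    for x, y, z in lm.points:
        out.append(f"{float(x)!r} {float(y)!r} {float(z)!r}")
    return "\n".join(out) + "\n"


def parse_tps(text: str, species: str = "", side: str = "right",
              structure: str = "cochlea_curve") -> LandmarkFile:
    """Minimal TPS-dialect reader (LM3= blocks with an ID= footer)."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].upper().startswith("LM3="):
        raise ParseError("TPS block must start with 'LM3='")
    n = int(lines[0].split("=", 1)[1])
    pts = []
    spec_id = ""
    for lineno, line in enumerate(lines[1:], start=2):
        if line.upper().startswith("ID="):
            spec_id = line.split("=", 1)[1]
            continue
        toks = line.split()
        if len(toks) != 3:
            raise ParseError(f"line {lineno}: expected 3 coordinates")
        pts.append([float(t) for t in toks])
    if len(pts) != n:
        raise ContentError(f"TPS header declares {n} points, found {len(pts)}")
    return LandmarkFile(spec_id or "unknown", species or "unknown", side,
                        structure, np.array(pts))


# --------------------------------------------------------------------- trees


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree; every edge must carry a length."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise ContentError("tree must have >= 2 tips")
    return Phylogeny(tree)


def read_newick(path: str | Path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def write_newick(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.as_newick() + "\n")


# -------------------------------------------------------------------- tables


def read_audiogram_table(path: str | Path) -> list[AudiogramRecord]:
    """Read a headed CSV (species,method,frequency_khz,threshold_db)."""
    df = pd.read_csv(path)
    required = {"species", "method", "frequency_khz", "threshold_db"}
    if not required.issubset(df.columns):
        raise ParseError(f"audiogram CSV must have columns {sorted(required)}")
    records = []
    for (species, method), grp in df.groupby(["species", "method"], sort=True):
        if method not in METHODS:
            raise ContentError(f"unknown method tag {method!r} for {species!r}")
        records.append(
            AudiogramRecord(
                species=str(species),
                method=str(method),
                frequencies_khz=grp["frequency_khz"].to_numpy(float),
                thresholds_db=grp["threshold_db"].to_numpy(float),
            )
        )
    return records


def write_audiogram_table(records: Iterable[AudiogramRecord], path: str | Path) -> None:
    rows = []
    for rec in sorted(records, key=lambda r: (r.species, r.method)):
        for f, t in rec.rows:
            rows.append((rec.species, rec.method, f, t))
    df = pd.DataFrame(rows, columns=["species", "method", "frequency_khz", "threshold_db"])
    df.to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Species-indexed scalar traits (body_mass_g, interaural_mm, group)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ParseError("trait CSV must have a 'species' column")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ContentError(f"duplicate species row(s): {dup}")
    return df.set_index("species").sort_index()


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.sort_index()
    out.to_csv(path, index=True, index_label="species", lineterminator="\n")


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path,
                  header_lines: Sequence[str] = ()) -> list[Path]:
    """Write each table as ``<name>.tsv``, species-sorted, deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        df = tables[name]
        if df.index.name == "species" or (df.index.name is None and df.index.dtype == object):
            df = df.sort_index()
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")
        written.append(path)
    return written
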