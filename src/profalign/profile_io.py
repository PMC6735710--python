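"""Readers and writers for complexome-profile tables and auxiliary files.

A profile table has one identifier column plus one numeric column per gel
slice.  Slice columns are taken in file order and interpreted as positions
along the lane; no molecular-mass calibration is attempted.  Empty cells
are read as zero, explicit NaN spellings are zeroed with a logged warning,
and any other non-numeric cell is an error.  Slice indices are 0-based
internally and 1-based in every written report.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_NAN_SPELLINGS = frozenset({"nan", "na", "n/a", "null", "none"})


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Profile:
    """One sample's protein x slice intensity matrix."""

    sample_id: str
    protein_ids: tuple[str, ...]
    intensities: np.ndarray  # shape (n_proteins, n_slices), float64, >= 0

    def __post_init__(self) -> None:
        ids = tuple(str(p) for p in self.protein_ids)
        mat = np.asarray(self.intensities, dtype=float)
        if mat.ndim != 2:
            raise ValueError(f"{self.sample_id}: intensities must be 2-D, got {mat.ndim}-D")
        if mat.shape[0] != len(ids):
            raise ValueError(
                f"{self.sample_id}: {len(ids)} protein ids but {mat.shape[0]} intensity rows"
            )
        if mat.shape[1] < 2:
            raise ValueError(f"{self.sample_id}: a profile needs at least 2 slices")
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"{self.sample_id}: non-finite intensity values")
        if np.any(mat < 0):
            raise ValueError(f"{self.sample_id}: negative intensity values")
        dupes = sorted(p for p, c in Counter(ids).items() if c > 1)
        if dupes:
            raise ValueError(f"{self.sample_id}: duplicate protein ids: {dupes}")
        object.__setattr__(self, "protein_ids", ids)
        object.__setattr__(self, "intensities", mat)

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[1]

    def total_intensity(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class ProfileSet:
    """Profiles harmonized to a shared, identically ordered protein roster."""

    profiles: tuple[Profile, ...]

    def __post_init__(self) -> None:
        profiles = tuple(self.profiles)
        if not profiles:
            raise ValueError("empty ProfileSet")
        sids = [p.sample_id for p in profiles]
        dupes = sorted(s for s, c in Counter(sids).items() if c > 1)
        if dupes:
            raise ValueError(f"duplicate sample ids: {dupes}")
        roster = profiles[0].protein_ids
        for p in profiles[1:]:
            if p.protein_ids != roster:
                raise ValueError(
                    f"sample {p.sample_id!r} roster differs; use build_profile_set() first"
                )
        object.__setattr__(self, "profiles", profiles)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(p.sample_id for p in self.profiles)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return self.profiles[0].protein_ids

    @property
    def n_samples(self) -> int:
        return len(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, sample_id: str) -> Profile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)


@dataclass(frozen=True)
class GroupAssignment:
    """Case/control labels for the samples of a ProfileSet."""

    case_ids: frozenset[str]
    control_ids: frozenset[str]

    def __post_init__(self) -> None:
        case = frozenset(self.case_ids)
        control = frozenset(self.control_ids)
        if not case or not control:
            raise ValueError("both groups must be non-empty")
        overlap = case & control
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")
        object.__setattr__(self, "case_ids", case)
        object.__setattr__(self, "control_ids", control)

    @property
    def all_ids(self) -> frozenset[str]:
        return self.case_ids | self.control_ids

    def validate_against(self, sample_ids: Sequence[str]) -> None:
        missing = sorted(self.all_ids - set(sample_ids))
        if missing:
            raise ValueError(f"group file names unknown samples: {missing}")
        unlabeled = sorted(set(sample_ids) - self.all_ids)
        if unlabeled:
            raise ValueError(f"samples without a group label: {unlabeled}")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named protein sets (e.g. complex memberships) for downstream reports."""

    sets: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for name, members in self.sets.items():
            members = tuple(str(m) for m in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[str(name)] = members
        if not clean:
            raise ValueError("no gene sets")
        object.__setattr__(self, "sets", clean)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# profile reading / writing


def _detect_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv"
        )
    if fmt not in ("csv", "tsv", "xlsx"):
        raise ValueError(f"unsupported format {fmt!r}")
    return fmt


def _read_table(path: Path, fmt: str) -> pd.DataFrame:
    if fmt == "xlsx":
        return pd.read_excel(path, dtype=object)
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _numeric_block(
    frame: pd.DataFrame, slice_cols: Sequence[str], ids: Sequence[str], path: Path
) -> np.ndarray:
    values = np.empty((len(frame), len(slice_cols)), dtype=float)
    n_nanlike = 0
    for j, col in enumerate(slice_cols):
        raw = frame[col]
        s = raw.where(raw.notna(), "").astype(str).str.strip()
        num = pd.to_numeric(s, errors="coerce")
        empty = (s == "").to_numpy()
        nanlike = s.str.lower().isin(_NAN_SPELLINGS).to_numpy()
        bad = num.isna().to_numpy() & ~empty & ~nanlike
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {s.iloc[i]!r} in slice column {col!r}, "
                f"row {ids[i]!r}"
            )
        col_values = num.to_numpy(dtype=float)
        col_values[empty | nanlike] = 0.0
        n_nanlike += int(nanlike.sum())
        values[:, j] = col_values
    if n_nanlike:
        log.warning("%s: %d explicit NaN cells read as 0", path, n_nanlike)
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = (int(k) for k in neg[0])
        raise ValueError(
            f"{path}: negative intensity {values[i, j]} for protein {ids[i]!r} "
            f"in slice column {slice_cols[j]!r}"
        )
    return values


def read_profile(
    path: str | Path,
    *,
    format: str | None = None,
    id_column: str = "protein_id",
    slice_columns: Sequence[str] | str = "auto",
    sample_id: str | None = None,
    gene_column: str | None = None,
) -> Profile:
    """Read one sample's profile table into a :class:`Profile`.

    With ``gene_column`` set, rows sharing a gene are collapsed to the row
    with the highest total intensity and the gene names become the protein
    ids (keep-max collapse of multiple proteins per gene).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile file not found: {path}")
    fmt = _detect_format(path, format)
    frame = _read_table(path, fmt)
    if id_column not in frame.columns:
        raise ValueError(f"{path}: id column {id_column!r} not found")
    if gene_column is not None and gene_column not in frame.columns:
        raise ValueError(f"{path}: gene column {gene_column!r} not found")

    if isinstance(slice_columns, str) and slice_columns == "auto":
        reserved = {id_column, gene_column}
        slice_cols = [c for c in frame.columns if c not in reserved]
    else:
        slice_cols = list(slice_columns)
        missing = [c for c in slice_cols if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: slice columns not found: {missing}")
    if len(slice_cols) < 2:
        raise ValueError(f"{path}: need at least 2 slice columns, got {len(slice_cols)}")

    ids = [str(v).strip() for v in frame[id_column]]
    dupes = sorted(p for p, c in Counter(ids).items() if c > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate entries in {id_column!r}: {dupes}")
    values = _numeric_block(frame, slice_cols, ids, path)

    if gene_column is not None:
        genes = [str(v).strip() for v in frame[gene_column]]
        totals = values.sum(axis=1)
        best: dict[str, int] = {}
        order: list[str] = []
        for i, g in enumerate(genes):
            if g not in best:
                best[g] = i
                order.append(g)
            elif totals[i] > totals[best[g]]:
                best[g] = i
        if len(order) < len(genes):
            log.info(
                "%s: collapsed %d rows to %d genes (keep max total intensity)",
                path, len(genes), len(order),
            )
        ids = order
        values = values[[best[g] for g in order], :]

    sid = sample_id if sample_id is not None else path.stem
    return Profile(sample_id=sid, protein_ids=tuple(ids), intensities=values)


def write_profile(
    profile: Profile, path: str | Path, *, format: str | None = None,
    id_column: str = "protein_id",
) -> Path:
    """Write a profile in the dialect :func:`read_profile` accepts."""
    path = Path(path)
    fmt = _detect_format(path, format)
    cols = [f"slice_{j + 1:03d}" for j in range(profile.n_slices)]
    frame = pd.DataFrame(profile.intensities, columns=cols)
    frame.insert(0, id_column, list(profile.protein_ids))
    if fmt == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, sep="," if fmt == "csv" else "\t", index=False)
    return path


def build_profile_set(
    profiles: Sequence[Profile], subset: Sequence[str] | None = None
) -> ProfileSet:
    """Harmonize profiles onto one protein roster (union order, zero fill).

    Proteins absent from a sample get an all-zero row there, so downstream
    local costs see presence/absence as intensity difference.  With
    ``subset`` the roster is restricted to the subset ids (in subset order)
    that occur in at least one profile.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    union: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        for pid in p.protein_ids:
            if pid not in seen:
                seen.add(pid)
                union.append(pid)
    if subset is not None:
        wanted = [str(s) for s in subset]
        roster = [pid for pid in wanted if pid in seen]
        if not roster:
            raise ValueError("subset shares no proteins with any profile")
        dropped = len(wanted) - len(roster)
        if dropped:
            log.info("subset: %d ids not present in any profile were dropped", dropped)
    else:
        roster = union

    harmonized = []
    for p in profiles:
        index = {pid: i for i, pid in enumerate(p.protein_ids)}
        mat = np.zeros((len(roster), p.n_slices), dtype=float)
        n_fill = 0
        for r, pid in enumerate(roster):
            i = index.get(pid)
            if i is None:
                n_fill += 1
            else:
                mat[r, :] = p.intensities[i, :]
        if n_fill:
            log.info("sample %s: %d proteins zero-filled", p.sample_id, n_fill)
        harmonized.append(
            Profile(sample_id=p.sample_id, protein_ids=tuple(roster), intensities=mat)
        )
    return ProfileSet(profiles=tuple(harmonized))


# ---------------------------------------------------------------------------
# auxiliary inputs


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a two-column sample -> case/control assignment file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"group file not found: {path}")
    case: set[str] = set()
    control: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", "\t").replace(";", "\t").split() if p]
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group', got {line!r}")
        sid, label = parts[0], parts[1].lower()
        if label == "case":
            case.add(sid)
        elif label == "control":
            control.add(sid)
        else:
            raise ValueError(
                f"{path}:{lineno}: group must be 'case' or 'control', got {parts[1]!r}"
            )
    return GroupAssignment(case_ids=frozenset(case), control_ids=frozenset(control))


def read_subset(path: str | Path) -> tuple[str, ...]:
    """Read a one-id-per-line protein inclusion list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"subset file not found: {path}")
    ids = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line.split()[0])
    if not ids:
        raise ValueError(f"{path}: empty subset file")
    return tuple(dict.fromkeys(ids))


def read_gene_sets(path: str | Path, *, format: str | None = None) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, members...) or two-column files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    fmt = format or ("gmt" if path.suffix.lower() == ".gmt" else "two-column")
    sets: dict[str, list[str]] = {}
    lines = [l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty gene set file")
    if fmt == "gmt":
        for lineno, line in enumerate(lines, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            members = [f for f in fields[2:] if f]
            if not members:
                raise ValueError(f"{path}: set {name!r} has no members")
            sets[name] = members
    elif fmt == "two-column":
        for lineno, line in enumerate(lines, start=1):
            parts = [p for p in line.replace(",", "\t").split() if p]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'set<TAB>member'")
            sets.setdefault(parts[0], [])
            if parts[1] not in sets[parts[0]]:
                sets[parts[0]].append(parts[1])
    else:
        raise ValueError(f"unsupported gene set format {fmt!r}")
    return GeneSetCollection(sets={k: tuple(v) for k, v in sets.items()})


# ---------------------------------------------------------------------------
# alignment output


def _positions_to_text(positions: np.ndarray) -> str:
    # 1-based in reports
    return ";".join(str(int(p) + 1) for p in positions)


def _positions_from_text(text: str) -> tuple[int, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(int(t) - 1 for t in text.split(";"))


def write_alignment(alignment, out_dir: str | Path, *, format: str = "csv") -> list[Path]:
    """Write warped per-sample matrices, the gap table, the pairwise cost
    matrix and the guide tree of a finalized alignment."""
    if format not in ("csv", "xlsx"):
        raise ValueError(f"unsupported alignment output format {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    L = alignment.length
    cols = [f"pos_{k + 1:03d}" for k in range(L)]
    for sid in alignment.sample_ids:
        frame = pd.DataFrame(
            alignment.matrices[sid], index=list(alignment.protein_ids), columns=cols
        )
        frame.index.name = "protein_id"
        p = out / f"aligned_{sid}.{'xlsx' if format == 'xlsx' else 'csv'}"
        if format == "xlsx":
            frame.to_excel(p)
        else:
            frame.to_csv(p)
        written.append(p)

    rows = []
    for sid in alignment.sample_ids:
        ins = alignment.insertions(sid)
        rows.append(
            {
                "sample_id": sid,
                "original_n_slices": L - len(ins),
                "aligned_length": L,
                "n_insertions": len(ins),
                "positions": _positions_to_text(ins),
            }
        )
    gaps = pd.DataFrame(rows)
    p = out / "insertions.csv"
    gaps.to_csv(p, index=False)
    written.append(p)

    if alignment.cost_matrix is not None:
        cm = pd.DataFrame(
            alignment.cost_matrix,
            index=list(alignment.sample_ids),
            columns=list(alignment.sample_ids),
        )
        cm.index.name = "sample_id"
        p = out / "cost_matrix.csv"
        cm.to_csv(p)
        written.append(p)

    if alignment.tree is not None:
        p = out / "guide_tree.newick"
        p.write_text(alignment.tree.newick() + "\n")
        written.append(p)
    return written


@dataclass(frozen=True)
class LoadedAlignment:
    """Alignment outputs re-read from disk; enough for distance computation."""

    sample_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    matrices: Mapping[str, np.ndarray]
    insertion_positions: Mapping[str, tuple[int, ...]]

    @property
    def length(self) -> int:
        return next(iter(self.matrices.values())).shape[1]

    def insertions(self, sample_id: str) -> np.ndarray:
        return np.asarray(self.insertion_positions[sample_id], dtype=int)


def read_alignment(out_dir: str | Path) -> LoadedAlignment:
    """Load the outputs of :func:`write_alignment` (CSV flavour)."""
    out = Path(out_dir)
    gap_path = out / "insertions.csv"
    if not gap_path.exists():
        raise FileNotFoundError(f"not an alignment directory (no insertions.csv): {out}")
    gaps = pd.read_csv(gap_path, dtype=str, keep_default_na=False)
    sample_ids = tuple(gaps["sample_id"])
    matrices: dict[str, np.ndarray] = {}
    protein_ids: tuple[str, ...] | None = None
    for sid in sample_ids:
        frame = pd.read_csv(out / f"aligned_{sid}.csv", index_col="protein_id")
        ids = tuple(str(i) for i in frame.index)
        if protein_ids is None:
            protein_ids = ids
        elif ids != protein_ids:
            raise ValueError(f"{out}: protein rosters differ between aligned files")
        matrices[sid] = frame.to_numpy(dtype=float)
    assert protein_ids is not None
    insertions = {
        sid: _positions_from_text(pos) for sid, pos in zip(sample_ids, gaps["positions"])
    }
    lengths = {m.shape[1] for m in matrices.values()}
    if len(lengths) != 1:
        raise ValueError(f"{out}: aligned matrices have differing lengths {sorted(lengths)}")
    return LoadedAlignment(
        sample_ids=sample_ids,
        protein_ids=protein_ids,
        matrices=matrices,
        insertion_positions=insertions,
    )
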