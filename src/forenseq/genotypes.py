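"""Data model and file I/O for multi-allelic diploid microsatellite genotypes.

Genotypes are unordered pairs of integer allele labels (fragment sizes in
base pairs).  A matrix holds samples x loci with an optional population
label per sample; reference individuals carry ``pop_known=True``, forensic
queries ``False``.  Three interchange formats are supported: GenePop,
STRUCTURE matrices (one- and two-row dialects) and a simple CSV with
``a/b`` cells.

Missing data is always "both alleles missing": half-calls are normalised to
fully missing on construction (the assignment formulas downstream are
defined on full diploid calls only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "Locus",
    "GenotypeMatrix",
    "AlleleFreqTable",
    "allele_frequencies",
    "read_genotypes",
    "write_genotypes",
]


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its ordered allele-size ladder."""

    name: str
    allele_labels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        labels = tuple(int(a) for a in self.allele_labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"locus {self.name!r}: duplicate allele labels")
        object.__setattr__(self, "allele_labels", tuple(sorted(labels)))


class GenotypeMatrix:
    """Samples x loci diploid calls with population metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers (opaque, case-sensitive strings).
    loci
        Ordered :class:`Locus` list.
    calls
        Integer array of shape ``(n_samples, n_loci, 2)``; allele pairs are
        stored sorted ascending and missing calls are ``(-1, -1)``.
    pop_labels
        Optional population identifier per sample (``None`` = unlabelled).
    pop_known
        Per-sample flag: ``True`` for reference individuals whose origin is
        trusted, ``False`` for query/forensic samples.  Defaults to
        ``pop_label is not None``.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
        pop_labels: Sequence[str | None] | None = None,
        pop_known: Sequence[bool] | None = None,
    ) -> None:
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(self.samples), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.samples)}, {len(self.loci)}, 2)"
            )
        # normalise: sort pairs, half-calls -> fully missing
        calls = np.sort(calls, axis=2)
        half = (calls[:, :, 0] == MISSING) & (calls[:, :, 1] != MISSING)
        if half.any():
            warnings.warn(
                f"{int(half.sum())} half-calls normalised to missing",
                stacklevel=2,
            )
            calls[half] = MISSING
        self.calls = calls
        if pop_labels is None:
            pop_labels = [None] * len(self.samples)
        self.pop_labels = list(pop_labels)
        if pop_known is None:
            pop_known = [lab is not None for lab in self.pop_labels]
        self.pop_known = np.asarray(pop_known, dtype=bool)
        if len(self.pop_labels) != len(self.samples) or len(self.pop_known) != len(
            self.samples
        ):
            raise ValueError("population metadata length mismatch")
        for i, known in enumerate(self.pop_known):
            if known and self.pop_labels[i] is None:
                raise ValueError(
                    f"sample {self.samples[i]!r} flagged pop_known without a label"
                )
        self._augment_ladders()

    # -- construction helpers -------------------------------------------------

    def _augment_ladders(self) -> None:
        """Ensure every observed allele is on its locus ladder."""
        new_loci = []
        for j, locus in enumerate(self.loci):
            observed = set(int(a) for a in self.calls[:, j, :].ravel() if a != MISSING)
            ladder = set(locus.allele_labels) | observed
            new_loci.append(Locus(locus.name, tuple(sorted(ladder))))
        self.loci = new_loci

    @classmethod
    def from_calls(
        cls,
        calls: Mapping[str, Mapping[str, tuple[int, int] | None]],
        locus_order: Sequence[str] | None = None,
        pop_labels: Mapping[str, str] | None = None,
        pop_known: Mapping[str, bool] | None = None,
    ) -> "GenotypeMatrix":
        """Build a matrix from a nested {sample: {locus: (a, b) | None}} map."""
        samples = list(calls)
        if locus_order is None:
            seen: dict[str, None] = {}
            for row in calls.values():
                for name in row:
                    seen.setdefault(name)
            locus_order = list(seen)
        arr = np.full((len(samples), len(locus_order), 2), MISSING, dtype=np.int32)
        for i, s in enumerate(samples):
            for j, name in enumerate(locus_order):
                pair = calls[s].get(name)
                if pair is not None:
                    arr[i, j] = sorted(pair)
        labels = [pop_labels.get(s) if pop_labels else None for s in samples]
        known = (
            [pop_known.get(s, labels[i] is not None) for i, s in enumerate(samples)]
            if pop_known
            else None
        )
        return cls(samples, [Locus(n) for n in locus_order], arr, labels, known)

    # -- basic queries ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def get_call(self, sample: str, locus: str) -> tuple[int, int] | None:
        i = self.samples.index(sample)
        j = self.locus_names.index(locus)
        a, b = self.calls[i, j]
        return None if a == MISSING else (int(a), int(b))

    def sample_row(self, sample: str) -> "GenotypeMatrix":
        return self.subset(samples=[sample])

    def populations(self) -> list[str]:
        """Known population labels in order of first appearance."""
        out: dict[str, None] = {}
        for lab, known in zip(self.pop_labels, self.pop_known):
            if known and lab is not None:
                out.setdefault(lab)
        return list(out)

    # -- manipulation ----------------------------------------------------------

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        s_idx = (
            [self.samples.index(s) for s in samples]
            if samples is not None
            else list(range(self.n_samples))
        )
        l_idx = (
            [self.locus_names.index(n) for n in loci]
            if loci is not None
            else list(range(self.n_loci))
        )
        return GenotypeMatrix(
            [self.samples[i] for i in s_idx],
            [self.loci[j] for j in l_idx],
            self.calls[np.ix_(s_idx, l_idx)],
            [self.pop_labels[i] for i in s_idx],
            [bool(self.pop_known[i]) for i in s_idx],
        )

    @classmethod
    def concat(cls, matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack matrices sharing the same locus names (ladders are merged)."""
        if not matrices:
            raise ValueError("nothing to concatenate")
        names = matrices[0].locus_names
        for m in matrices[1:]:
            if m.locus_names != names:
                raise ValueError("locus sets differ between matrices")
        return cls(
            [s for m in matrices for s in m.samples],
            [Locus(n) for n in names],
            np.concatenate([m.calls for m in matrices], axis=0),
            [lab for m in matrices for lab in m.pop_labels],
            [bool(k) for m in matrices for k in m.pop_known],
        )

    def __eq__(self, other: object) -> bool:
        """Equality on samples, locus names, calls and population metadata.

        Allele ladders are reconstructed metadata and deliberately excluded.
        """
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
            and self.pop_labels == other.pop_labels
            and np.array_equal(self.pop_known, other.pop_known)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci, "
            f"pops={self.populations()!r})"
        )


@dataclass
class AlleleFreqTable:
    """Observed allele frequencies per (population, locus).

    ``freqs[pop][locus][allele]`` is the relative frequency among observed
    gene copies; ``gene_copies[pop][locus]`` is the denominator.  A
    (population, locus) cell with zero gene copies is *unavailable* and is
    absent from both maps.
    """

    freqs: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    gene_copies: dict[str, dict[str, int]] = field(default_factory=dict)
    dataset_alleles: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.freqs)

    def available(self, pop: str, locus: str) -> bool:
        return self.gene_copies.get(pop, {}).get(locus, 0) > 0

    def freq(self, pop: str, locus: str, allele: int) -> float:
        return self.freqs.get(pop, {}).get(locus, {}).get(allele, 0.0)

    def counts(self, pop: str, locus: str) -> dict[int, int]:
        """Integer allele counts (frequency x gene copies), rounded."""
        n = self.gene_copies.get(pop, {}).get(locus, 0)
        return {
            a: int(round(f * n)) for a, f in self.freqs.get(pop, {}).get(locus, {}).items()
        }


def allele_frequencies(g: GenotypeMatrix, by_pop: bool = True) -> AlleleFreqTable:
    """Tally allele frequencies, excluding missing calls entirely.

    With ``by_pop=True`` only samples with a known population contribute,
    each to its own population; with ``by_pop=False`` all samples pool into
    a single population ``"_all"``.
    """
    table = AlleleFreqTable()
    for j, locus in enumerate(g.loci):
        observed = set(int(a) for a in g.calls[:, j, :].ravel() if a != MISSING)
        table.dataset_alleles[locus.name] = tuple(sorted(observed))
    if by_pop:
        groups = {
            pop: [i for i in range(g.n_samples) if g.pop_known[i] and g.pop_labels[i] == pop]
            for pop in g.populations()
        }
    else:
        groups = {"_all": list(range(g.n_samples))}
    for pop, idx in groups.items():
        table.freqs[pop] = {}
        table.gene_copies[pop] = {}
        for j, locus in enumerate(g.loci):
            alleles = g.calls[idx, j, :].ravel()
            alleles = alleles[alleles != MISSING]
            if alleles.size == 0:
                continue
            vals, counts = np.unique(alleles, return_counts=True)
            total = int(alleles.size)
            table.freqs[pop][locus.name] = {
                int(v): float(c) / total for v, c in zip(vals, counts)
            }
            table.gene_copies[pop][locus.name] = total
    return table


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

FORMATS = ("genepop", "structure", "csv")


class GenotypeParseError(ValueError):
    """Malformed genotype file; message names the offending line."""


def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the named dialect.

    Supported dialects: ``genepop`` (2- or 3-digit allele codes,
    auto-detected; ``0000``/``000000`` missing), ``structure`` (locus-name
    header, one-row-two-columns or two-rows-per-individual, ``-9`` missing)
    and ``csv`` (samples x loci, ``a/b`` cells, empty = missing).
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    text = path.read_text()
    if format == "genepop":
        return _read_genepop(text)
    if format == "structure":
        return _read_structure(text)
    return _read_csv(text)


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str) -> None:
    """Write ``g`` to ``path``; ``read_genotypes`` round-trips the result."""
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "genepop":
        path.write_text(_to_genepop(g))
    elif format == "structure":
        path.write_text(_to_structure(g))
    else:
        path.write_text(_to_csv(g))


# -- GenePop -----------------------------------------------------------------


def _to_genepop(g: GenotypeMatrix) -> str:
    """GenePop dialect notes: population labels are carried as a
    ``label|sample`` prefix on the individual name (the format itself has no
    label field); all samples must have a known population."""
    width = 3
    for locus in g.loci:
        for a in locus.allele_labels:
            if not 1 <= a <= 999:
                raise ValueError(
                    f"allele {a} at locus {locus.name} not representable "
                    "as a 3-digit GenePop code"
                )
    if not all(g.pop_known):
        raise ValueError(
            "GenePop requires population structure; samples with unknown "
            "origin cannot be written (use the structure or csv format)"
        )
    lines = ["forenseq genotype export"]
    lines.extend(g.locus_names)
    by_pop: dict[str, list[int]] = {}
    for i, lab in enumerate(g.pop_labels):
        by_pop.setdefault(str(lab), []).append(i)
    miss = "0" * (2 * width)
    for lab, idx in by_pop.items():
        lines.append("Pop")
        for i in idx:
            codes = []
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                codes.append(miss if a == MISSING else f"{a:0{width}d}{b:0{width}d}")
            lines.append(f"{lab}|{g.samples[i]} , " + " ".join(codes))
    return "\n".join(lines) + "\n"


def _read_genepop(text: str) -> GenotypeMatrix:
    raw = text.splitlines()
    lines = [ln for ln in raw if ln.strip()]
    if len(lines) < 3:
        raise GenotypeParseError("GenePop file too short: need title, loci, Pop")
    # loci: lines after the title up to the first "Pop"; allow comma-separated
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError("GenePop file has no 'Pop' line")
    samples: list[str] = []
    pops: list[str | None] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    block = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            block += 1
            i += 1
            continue
        line = lines[i]
        if "," not in line:
            raise GenotypeParseError(f"line {raw.index(line) + 1}: expected 'name , codes'")
        name, _, rest = line.partition(",")
        name = name.strip()
        if "|" in name:
            pop, _, name = name.partition("|")
        else:
            pop = f"Pop{block}"
        codes = rest.split()
        if len(codes) != len(locus_names):
            raise GenotypeParseError(
                f"line {raw.index(line) + 1}: {len(codes)} genotypes for "
                f"{len(locus_names)} loci"
            )
        row: list[tuple[int, int]] = []
        for code in codes:
            if len(code) not in (4, 6) or not code.isdigit():
                raise GenotypeParseError(
                    f"line {raw.index(line) + 1}: bad genotype code {code!r}"
                )
            if set(code) == {"0"}:  # missing: either-width all-zero code
                row.append((MISSING, MISSING))
                continue
            w = len(code) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenotypeParseError(
                    f"line {raw.index(line) + 1}: mixed allele code widths"
                )
            a, b = int(code[:w]), int(code[w:])
            row.append((MISSING, MISSING) if a == 0 or b == 0 else (a, b))
        samples.append(name)
        pops.append(pop)
        rows.append(row)
        i += 1
    arr = np.array(rows, dtype=np.int32).reshape(len(samples), len(locus_names), 2)
    return GenotypeMatrix(samples, [Locus(n) for n in locus_names], arr, pops)


# -- STRUCTURE ---------------------------------------------------------------


def _to_structure(g: GenotypeMatrix, two_row: bool = False) -> str:
    for s in g.samples:
        if any(ch.isspace() for ch in s):
            raise ValueError(f"sample id {s!r} contains whitespace")
    header = " ".join(g.locus_names)
    lines = [header]
    for i, s in enumerate(g.samples):
        pop = g.pop_labels[i] if g.pop_labels[i] is not None else "-"
        flag = "1" if g.pop_known[i] else "0"
        if two_row:
            for c in (0, 1):
                vals = [
                    "-9" if g.calls[i, j, 0] == MISSING else str(g.calls[i, j, c])
                    for j in range(g.n_loci)
                ]
                lines.append(" ".join([s, str(pop), flag] + vals))
        else:
            vals = []
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                vals += ["-9", "-9"] if a == MISSING else [str(a), str(b)]
            lines.append(" ".join([s, str(pop), flag] + vals))
    return "\n".join(lines) + "\n"


def _read_structure(text: str) -> GenotypeMatrix:
    raw = [ln for ln in text.splitlines() if ln.strip()]
    if len(raw) < 2:
        raise GenotypeParseError("STRUCTURE file too short")
    locus_names = raw[0].split()
    nl = len(locus_names)
    data = [ln.split() for ln in raw[1:]]
    widths = {len(row) for row in data}
    if len(widths) != 1:
        raise GenotypeParseError("ragged STRUCTURE rows: inconsistent column counts")
    width = widths.pop()
    candidates = []
    for extras in (3, 1):
        if width == extras + 2 * nl:
            candidates.append(("one", extras))
        if width == extras + nl:
            candidates.append(("two", extras))
    if not candidates:
        raise GenotypeParseError(
            f"STRUCTURE row width {width} matches neither one-row ({3 + 2 * nl}) "
            f"nor two-row ({3 + nl}) layout for {nl} loci"
        )
    if len(candidates) > 1:
        # ambiguous widths (possible when nl==2): two-row files repeat ids
        paired = len(data) % 2 == 0 and all(
            data[k][0] == data[k + 1][0] for k in range(0, len(data), 2)
        )
        candidates = [c for c in candidates if (c[0] == "two") == paired]
    layout, extras = candidates[0]

    def meta(row: list[str]) -> tuple[str, str | None, bool]:
        if extras == 3:
            pop = None if row[1] == "-" else row[1]
            return row[0], pop, row[2] == "1"
        return row[0], None, False

    samples: list[str] = []
    pops: list[str | None] = []
    known: list[bool] = []
    rows: list[np.ndarray] = []
    if layout == "one":
        for row in data:
            s, pop, flag = meta(row)
            try:
                vals = np.array([int(v) for v in row[extras:]], dtype=np.int32)
            except ValueError as e:
                raise GenotypeParseError(f"non-integer allele in row for {s!r}") from e
            pair = vals.reshape(nl, 2)
            pair[(pair == -9).any(axis=1)] = MISSING
            samples.append(s)
            pops.append(pop)
            known.append(flag)
            rows.append(pair)
    else:
        if len(data) % 2:
            raise GenotypeParseError("two-row STRUCTURE file with odd row count")
        for k in range(0, len(data), 2):
            r1, r2 = data[k], data[k + 1]
            if r1[0] != r2[0]:
                raise GenotypeParseError(
                    f"two-row pair mismatch: {r1[0]!r} followed by {r2[0]!r}"
                )
            s, pop, flag = meta(r1)
            v1 = np.array([int(v) for v in r1[extras:]], dtype=np.int32)
            v2 = np.array([int(v) for v in r2[extras:]], dtype=np.int32)
            pair = np.stack([v1, v2], axis=1)
            pair[(pair == -9).any(axis=1)] = MISSING
            samples.append(s)
            pops.append(pop)
            known.append(flag)
            rows.append(pair)
    arr = np.stack(rows).astype(np.int32)
    arr[arr == -9] = MISSING
    return GenotypeMatrix(samples, [Locus(n) for n in locus_names], arr, pops, known)


# -- CSV ---------------------------------------------------------------------


def _to_csv(g: GenotypeMatrix) -> str:
    rows = []
    for i, s in enumerate(g.samples):
        row: dict[str, str] = {
            "sample": s,
            "pop": "" if g.pop_labels[i] is None else str(g.pop_labels[i]),
            "pop_known": "1" if g.pop_known[i] else "0",
        }
        for j, name in enumerate(g.locus_names):
            a, b = g.calls[i, j]
            row[name] = "" if a == MISSING else f"{a}/{b}"
        rows.append(row)
    df = pd.DataFrame(rows, columns=["sample", "pop", "pop_known"] + g.locus_names)
    return df.to_csv(index=False)


def _read_csv(text: str) -> GenotypeMatrix:
    import io

    df = pd.read_csv(io.StringIO(text), dtype=str).fillna("")
    if "sample" not in df.columns:
        raise GenotypeParseError("CSV lacks a 'sample' column")
    meta_cols = [c for c in ("sample", "pop", "pop_known") if c in df.columns]
    locus_names = [c for c in df.columns if c not in meta_cols]
    samples = df["sample"].tolist()
    pops = [p if p != "" else None for p in df.get("pop", pd.Series([""] * len(df)))]
    if "pop_known" in df.columns:
        known = [v == "1" for v in df["pop_known"]]
    else:
        known = [p is not None for p in pops]
    arr = np.full((len(samples), len(locus_names), 2), MISSING, dtype=np.int32)
    for i in range(len(samples)):
        for j, name in enumerate(locus_names):
            cell = str(df.iloc[i][name]).strip()
            if not cell:
                continue
            if "/" not in cell:
                raise GenotypeParseError(
                    f"row {i + 2}: cell {cell!r} at locus {name} is not 'a/b'"
                )
            a, b = cell.split("/", 1)
            try:
                arr[i, j] = sorted((int(a), int(b)))
            except ValueError as e:
                raise GenotypeParseError(
                    f"row {i + 2}: non-integer allele in {cell!r}"
                ) from e
    return GenotypeMatrix(samples, [Locus(n) for n in locus_names], arr, pops, known)
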