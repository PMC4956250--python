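"""Data model and I/O for diploid microsatellite genotype datasets.

Alleles are identified by their fragment size in base pairs throughout the
package; conversion to the repeat-unit lattice happens only where a lattice is
genuinely required (M-ratio, stepwise-mutation simulators).  Missing data is a
dataset-level sentinel (:data:`MISSING`), excluded from every frequency
denominator; nothing in the package imputes genotypes.
"""

from __future__ import annotations

import io
import json
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call (both alleles of a genotype are either
#: present or :data:`MISSING`; a half-called genotype is invalid).
MISSING = -1

_STATUSES = ("indigenous", "cultivated", "naturalised")


class ParseError(ValueError):
    """Raised on malformed genotype input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker.

    Parameters
    ----------
    name
        Marker identifier, unique within a dataset.
    motif_length
        Length of the repeat unit in bp (>= 1); needed wherever allele sizes
        must be placed on the repeat-unit lattice.
    size_range
        Optional (min bp, max bp) of the scorable fragment range.
    """

    name: str
    motif_length: int = 2
    size_range: tuple[int, int] | None = None

    def __post_init__(self):
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")


@dataclass(frozen=True)
class PopulationInfo:
    """Sampling-site metadata for one population."""

    id: str
    locality: str = ""
    country: str = ""
    status: str = "indigenous"
    latitude: float = 0.0
    longitude: float = 0.0
    n: int = 0

    def __post_init__(self):
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}, got {self.status!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


class GenotypeDataset:
    """Individuals x loci diploid allele-size calls with population membership.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` holding allele sizes in
    bp, with :data:`MISSING` for untyped cells.  ``pop_index[i]`` maps
    individual ``i`` to ``populations[pop_index[i]]``.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        populations: Sequence[PopulationInfo],
        calls: np.ndarray,
        pop_index: np.ndarray,
    ):
        self.loci = list(loci)
        self.populations = list(populations)
        self.calls = np.asarray(calls, dtype=np.int64)
        self.pop_index = np.asarray(pop_index, dtype=np.int64)
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        pids = [p.id for p in self.populations]
        if len(set(pids)) != len(pids):
            raise ValueError("population ids must be unique")
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError(f"calls must be (n, L, 2), got {self.calls.shape}")
        if self.calls.shape[1] != len(self.loci):
            raise ValueError("calls second axis must match number of loci")
        if self.calls.shape[0] != self.pop_index.shape[0]:
            raise ValueError("pop_index length must match number of individuals")
        if self.pop_index.size and (
            self.pop_index.min() < 0 or self.pop_index.max() >= len(self.populations)
        ):
            raise ValueError("pop_index out of range")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype at individual {i}, locus {self.loci[l].name}"
            )
        bad = (self.calls != MISSING) & (self.calls <= 0)
        if bad.any():
            raise ValueError("allele sizes must be positive")
        if self.calls.shape[0]:
            untyped = (self.calls[:, :, 0] == MISSING).all(axis=1)
            if untyped.any():
                raise ValueError(
                    f"individual {int(np.argmax(untyped))} has no non-missing call"
                )

    # -- basic accessors -----------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def locus_index(self, locus: str | int) -> int:
        if isinstance(locus, (int, np.integer)):
            return int(locus)
        for i, loc in enumerate(self.loci):
            if loc.name == locus:
                return i
        raise KeyError(f"no such locus: {locus!r}")

    def population_index(self, population: str | int) -> int:
        if isinstance(population, (int, np.integer)):
            return int(population)
        for i, p in enumerate(self.populations):
            if p.id == population:
                return i
        raise KeyError(f"no such population: {population!r}")

    def individuals_of(self, population: str | int) -> np.ndarray:
        """Row indices of the individuals belonging to one population."""
        return np.flatnonzero(self.pop_index == self.population_index(population))

    def pop_sizes(self) -> np.ndarray:
        return np.bincount(self.pop_index, minlength=self.n_populations)

    # -- counting ------------------------------------------------------------------

    def allele_counts(self, population: str | int, locus: str | int) -> dict[int, int]:
        """Counts of each allele (size in bp) over non-missing gene copies.

        The counts sum to twice the number of typed individuals in the cell;
        an all-missing cell yields an empty mapping.
        """
        li = self.locus_index(locus)
        rows = self.individuals_of(population)
        copies = self.calls[rows, li, :].ravel()
        copies = copies[copies != MISSING]
        return dict(sorted(Counter(copies.tolist()).items()))

    def pooled_allele_counts(self, locus: str | int) -> dict[int, int]:
        li = self.locus_index(locus)
        copies = self.calls[:, li, :].ravel()
        copies = copies[copies != MISSING]
        return dict(sorted(Counter(copies.tolist()).items()))

    def n_typed(self, population: str | int, locus: str | int) -> int:
        """Number of typed (non-missing) individuals in a population x locus cell."""
        li = self.locus_index(locus)
        rows = self.individuals_of(population)
        return int((self.calls[rows, li, 0] != MISSING).sum())

    def repeat_units(self, locus: str | int, sizes: Iterable[int] | None = None) -> np.ndarray:
        """Map allele sizes to integer repeat-unit lattice coordinates.

        Coordinates are ``floor((size - min_observed)/motif)`` where
        ``min_observed`` is the smallest allele observed dataset-wide at the
        locus; the map is monotone in size.  Sizes below the observed minimum
        raise.
        """
        li = self.locus_index(locus)
        observed = self.calls[:, li, :].ravel()
        observed = observed[observed != MISSING]
        if observed.size == 0:
            raise ValueError(f"locus {self.loci[li].name} has no typed calls")
        lo = int(observed.min())
        if sizes is None:
            sizes_arr = observed
        else:
            sizes_arr = np.asarray(list(sizes), dtype=np.int64)
            if (sizes_arr < lo).any():
                raise ValueError(f"allele size below observed minimum {lo}")
        return (sizes_arr - lo) // self.loci[li].motif_length

    # -- subsetting ----------------------------------------------------------------

    def subset_populations(self, keep: Sequence[str | int]) -> "GenotypeDataset":
        """New dataset restricted to the given populations (order as given).

        Per-individual genotypes are preserved bit-exactly.
        """
        idx = [self.population_index(p) for p in keep]
        rows: list[np.ndarray] = []
        new_pi: list[int] = []
        for new_k, old_k in enumerate(idx):
            r = np.flatnonzero(self.pop_index == old_k)
            rows.append(r)
            new_pi.extend([new_k] * len(r))
        rows_arr = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
        return GenotypeDataset(
            self.loci,
            [self.populations[k] for k in idx],
            self.calls[rows_arr].copy(),
            np.asarray(new_pi, dtype=np.int64),
        )

    def status_groups(self) -> dict[str, list[str]]:
        """Population ids grouped by status, cultivated+naturalised merged.

        Returns ``{"indigenous": [...], "cultivated_naturalised": [...]}`` —
        the two-group comparison used throughout the diversity analyses.
        """
        ind = [p.id for p in self.populations if p.status == "indigenous"]
        cn = [p.id for p in self.populations if p.status != "indigenous"]
        return {"indigenous": ind, "cultivated_naturalised": cn}

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            [l.name for l in self.loci] == [l.name for l in other.loci]
            and [p.id for p in self.populations] == [p.id for p in other.populations]
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.pop_index, other.pop_index)
        )


# -- GENEPOP format --------------------------------------------------------------


def _code_width(dataset: GenotypeDataset) -> int:
    mx = int(dataset.calls.max(initial=0))
    return 3 if mx > 99 else 2


def write_genepop(dataset: GenotypeDataset, title: str = "msatpop export") -> str:
    """Serialize to GENEPOP v4 text (2- or 3-digit codes chosen by allele size)."""
    w = _code_width(dataset)
    if int(dataset.calls.max(initial=0)) >= 10**w:
        raise ValueError("allele sizes exceed 3-digit GENEPOP coding")
    out = io.StringIO()
    out.write(title + "\n")
    for loc in dataset.loci:
        out.write(loc.name + "\n")
    for k, pop in enumerate(dataset.populations):
        out.write("POP\n")
        for i in dataset.individuals_of(k):
            parts = []
            for l in range(dataset.n_loci):
                a, b = dataset.calls[i, l]
                if a == MISSING:
                    parts.append("0" * (2 * w))
                else:
                    parts.append(f"{a:0{w}d}{b:0{w}d}")
            out.write(f"{pop.id}_{i:04d} ,  " + " ".join(parts) + "\n")
    return out.getvalue()


def read_genepop(
    text: str,
    motif_lengths: Mapping[str, int] | None = None,
    population_info: Sequence[PopulationInfo] | None = None,
) -> GenotypeDataset:
    """Parse GENEPOP v4 text into a :class:`GenotypeDataset`.

    The allele-code width (2 or 3 digits) is inferred from the first genotype
    token; ``0``/``000`` decodes to :data:`MISSING`.  Population metadata not
    carried by the format can be supplied via ``population_info``; otherwise
    populations are named ``P01``, ``P02``, ... in file order.
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ParseError("empty GENEPOP input (missing title line)", 1)
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        row = lines[i].strip()
        if row:
            # loci may be one-per-line or comma separated
            locus_names.extend(s.strip() for s in row.split(",") if s.strip())
        i += 1
    if not locus_names:
        raise ParseError("no locus names before first POP", i)
    if i >= len(lines):
        raise ParseError("no POP section found", len(lines))

    pops: list[list[list[int]]] = []
    width: int | None = None
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pops.append([])
            i += 1
            continue
        row = lines[i].strip()
        if not row:
            i += 1
            continue
        if "," not in row:
            raise ParseError("genotype row lacks ',' separator", i + 1)
        _, geno = row.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"expected {len(locus_names)} genotype fields, got {len(tokens)}", i + 1
            )
        alleles: list[int] = []
        for tok in tokens:
            if not re.fullmatch(r"\d+", tok):
                raise ParseError(f"non-numeric genotype field {tok!r}", i + 1)
            if width is None:
                if len(tok) == 4:
                    width = 2
                elif len(tok) == 6:
                    width = 3
                else:
                    raise ParseError(
                        f"cannot infer allele-code width from field {tok!r}", i + 1
                    )
            if len(tok) != 2 * width:
                raise ParseError(
                    f"genotype field {tok!r} does not match code width {width}", i + 1
                )
            a, b = int(tok[:width]), int(tok[width:])
            if (a == 0) != (b == 0):
                raise ParseError(f"half-missing genotype {tok!r}", i + 1)
            alleles.extend([MISSING if a == 0 else a, MISSING if b == 0 else b])
        pops[-1].append(alleles)
        i += 1

    calls_rows: list[list[int]] = []
    pop_index: list[int] = []
    infos: list[PopulationInfo] = []
    for k, rows in enumerate(pops):
        if population_info is not None:
            info = population_info[k]
        else:
            info = PopulationInfo(id=f"P{k + 1:02d}", n=len(rows))
        infos.append(info)
        for r in rows:
            calls_rows.append(r)
            pop_index.append(k)
    calls = np.asarray(calls_rows, dtype=np.int64).reshape(len(calls_rows), len(locus_names), 2)
    motif_lengths = motif_lengths or {}
    loci = [Locus(nm, motif_lengths.get(nm, 2)) for nm in locus_names]
    return GenotypeDataset(loci, infos, calls, np.asarray(pop_index, dtype=np.int64))


# -- tabular (CSV) format --------------------------------------------------------


def write_genotype_table(dataset: GenotypeDataset) -> str:
    """CSV with one row per individual, two columns per locus, pop label column."""
    cols: dict[str, list] = {"population": []}
    for loc in dataset.loci:
        cols[f"{loc.name}_1"] = []
        cols[f"{loc.name}_2"] = []
    for i in range(dataset.n_individuals):
        cols["population"].append(dataset.populations[dataset.pop_index[i]].id)
        for l, loc in enumerate(dataset.loci):
            a, b = dataset.calls[i, l]
            cols[f"{loc.name}_1"].append(int(a) if a != MISSING else 0)
            cols[f"{loc.name}_2"].append(int(b) if b != MISSING else 0)
    return pd.DataFrame(cols).to_csv(index=False)


def read_genotype_table(
    source,
    metadata: Sequence[PopulationInfo] | None = None,
    motif_lengths: Mapping[str, int] | None = None,
) -> GenotypeDataset:
    """Read a genotype table: one row per individual, two allele columns per locus.

    ``source`` is a path or file-like accepted by :func:`pandas.read_csv`.  The
    table must carry a ``population`` label column; remaining columns are taken
    pairwise as the two allele sizes (bp) of consecutive loci, named by
    stripping a ``_1``/``_2`` suffix.  Zeros decode to :data:`MISSING`.
    """
    df = pd.read_csv(source)
    if df.empty:
        raise ParseError("empty genotype table")
    pop_col = None
    for cand in ("population", "pop", "Population"):
        if cand in df.columns:
            pop_col = cand
            break
    if pop_col is None:
        raise ParseError("no population label column found")
    allele_cols = [c for c in df.columns if c != pop_col]
    if len(allele_cols) % 2 != 0:
        raise ParseError(f"odd number of allele columns ({len(allele_cols)})")
    locus_names = []
    for j in range(0, len(allele_cols), 2):
        name = re.sub(r"[_.]?[12aAbB]$", "", allele_cols[j])
        locus_names.append(name if name else allele_cols[j])

    labels = df[pop_col].astype(str).tolist()
    if metadata is not None:
        known = {p.id: k for k, p in enumerate(metadata)}
        missing_meta = sorted(set(labels) - set(known))
        if missing_meta:
            raise ParseError(f"population labels absent from metadata: {missing_meta}")
        infos = list(metadata)
        pop_index = np.asarray([known[x] for x in labels], dtype=np.int64)
    else:
        order = list(dict.fromkeys(labels))
        known = {pid: k for k, pid in enumerate(order)}
        pop_index = np.asarray([known[x] for x in labels], dtype=np.int64)
        sizes = np.bincount(pop_index, minlength=len(order))
        infos = [PopulationInfo(id=pid, n=int(sizes[k])) for k, pid in enumerate(order)]

    raw = df[allele_cols].to_numpy(dtype=np.int64).reshape(len(df), len(locus_names), 2)
    calls = np.where(raw == 0, MISSING, raw)
    motif_lengths = motif_lengths or {}
    loci = [Locus(nm, motif_lengths.get(nm, 2)) for nm in locus_names]
    return GenotypeDataset(loci, infos, calls, pop_index)


# -- metadata sidecar ------------------------------------------------------------


def population_info_to_json(populations: Sequence[PopulationInfo]) -> str:
    return json.dumps([p.__dict__ for p in populations], indent=1)


def population_info_from_json(text: str) -> list[PopulationInfo]:
    return [PopulationInfo(**d) for d in json.loads(text)]


def population_info_from_table(df: pd.DataFrame) -> list[PopulationInfo]:
    """Build metadata from a table with id/locality/country/status/lat/lon/n columns."""
    out = []
    for _, row in df.iterrows():
        out.append(
            PopulationInfo(
                id=str(row["id"]),
                locality=str(row.get("locality", "")),
                country=str(row.get("country", "")),
                status=str(row["status"]).lower(),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                n=int(row["n"]),
            )
        )
    return out


def structure_export(dataset: GenotypeDataset) -> str:
    """One-row-per-allele-copy export compatible with admixture-clustering tools.

    Columns: individual label, population index (1-based), then one allele size
    per locus; missing coded as -9; two rows per individual.
    """
    out = io.StringIO()
    out.write("\t".join(loc.name for loc in dataset.loci) + "\n")
    for i in range(dataset.n_individuals):
        label = f"ind{i:04d}"
        for c in range(2):
            row = [label, str(int(dataset.pop_index[i]) + 1)]
            for l in range(dataset.n_loci):
                a = int(dataset.calls[i, l, c])
                row.append(str(a if a != MISSING else -9))
            out.write("\t".join(row) + "\n")
    return out.getvalue()
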