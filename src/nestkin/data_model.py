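"""Core domain types and file I/O for microsatellite nesting studies.

The package operates on three objects: a :class:`GenotypePanel` (diploid
multilocus genotypes with design labels), a :class:`PointPattern` (planar nest
coordinates inside a rectangular observation window, meters), and a
:class:`StudyDesign` (the nested mapping individual -> nest -> cluster ->
nesting site -> population). Genotypes travel as Genepop files or a wide CSV
dialect; coordinates and designs as plain CSV.

Allele codes are opaque positive integers; code 0 means missing. Missing
genotypes are all-or-nothing: a half-called genotype is demoted to fully
missing on construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "GenotypePanel",
    "PointPattern",
    "StudyDesign",
    "ValidationReport",
    "read_genepop",
    "write_genepop",
    "read_coordinates",
    "read_design",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "validate_study",
    "one_hatchling_per_nest",
]

LABEL_COLUMNS = ["population", "nesting_site", "cluster", "nest", "life_stage"]


class GenotypeParseError(ValueError):
    """Malformed genotype file; message names the offending line."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    ``allele_length`` is the number of digits per allele in the fused Genepop
    encoding (2 or 3; default 3).
    """

    name: str
    allele_length: int = 3

    def __post_init__(self):
        if self.allele_length not in (2, 3):
            raise ValueError(f"allele_length must be 2 or 3, got {self.allele_length}")


@dataclass
class GenotypePanel:
    """Diploid genotypes for a set of individuals at a set of loci.

    Parameters
    ----------
    individuals : list of str
        Ordered sample identifiers (unique).
    loci : list of Locus
        Ordered loci (unique names).
    calls : ndarray of shape (n_individuals, n_loci, 2), dtype int
        Unordered allele pairs; 0 encodes missing (both entries 0).
    labels : pandas.DataFrame
        Indexed by individual; columns from ``LABEL_COLUMNS`` (missing columns
        are added as NA). ``life_stage`` is "adult" or "hatchling" when known.
    """

    individuals: list
    loci: list
    calls: np.ndarray
    labels: pd.DataFrame = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if (self.calls < 0).any():
            raise ValueError("allele codes must be nonnegative integers")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual ids")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != m:
            raise ValueError("duplicate locus names")
        # enforce all-or-nothing missing
        half = (self.calls == 0).any(axis=2) & ~(self.calls == 0).all(axis=2)
        if half.any():
            self.calls = self.calls.copy()
            self.calls[half] = 0
        if self.labels is None:
            self.labels = pd.DataFrame(index=pd.Index(self.individuals, name="id"))
        else:
            self.labels = self.labels.reindex(self.individuals)
        for col in LABEL_COLUMNS:
            if col not in self.labels.columns:
                self.labels[col] = pd.NA

    # -- basic views -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list:
        return [loc.name for loc in self.loci]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the genotype is missing."""
        return (self.calls == 0).all(axis=2)

    def subset_individuals(self, ids) -> "GenotypePanel":
        idx = {ind: i for i, ind in enumerate(self.individuals)}
        rows = [idx[i] for i in ids]
        return GenotypePanel(
            list(ids), list(self.loci), self.calls[rows], self.labels.loc[list(ids)]
        )

    def subset_by_label(self, column: str, value) -> "GenotypePanel":
        keep = [
            ind
            for ind in self.individuals
            if self.labels.loc[ind, column] == value
        ]
        return self.subset_individuals(keep)

    def subset_loci(self, names) -> "GenotypePanel":
        pos = {loc.name: j for j, loc in enumerate(self.loci)}
        cols = [pos[nm] for nm in names]
        return GenotypePanel(
            list(self.individuals),
            [self.loci[j] for j in cols],
            self.calls[:, cols],
            self.labels,
        )


@dataclass
class PointPattern:
    """Nest coordinates (meters, projected planar) in a rectangular window."""

    ids: list
    xy: np.ndarray
    window: tuple  # (xmin, xmax, ymin, ymax)
    year: np.ndarray = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.ids) != len(self.xy):
            raise ValueError("ids and xy length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate point ids")
        if not np.isfinite(self.xy).all():
            raise ValueError("coordinates must be finite")
        xmin, xmax, ymin, ymax = self.window
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("window must have positive area")
        x, y = self.xy[:, 0], self.xy[:, 1]
        if len(x) and (
            (x < xmin).any() or (x > xmax).any() or (y < ymin).any() or (y > ymax).any()
        ):
            raise ValueError("points outside the observation window")
        if self.year is not None:
            self.year = np.asarray(self.year)
            if len(self.year) != len(self.ids):
                raise ValueError("year length mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def area(self) -> float:
        xmin, xmax, ymin, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)

    @property
    def intensity(self) -> float:
        """Estimated intensity lambda = n / area (points per square meter)."""
        return self.n / self.area

    def subset(self, mask) -> "PointPattern":
        mask = np.asarray(mask)
        ids = [i for i, m in zip(self.ids, mask) if m]
        year = self.year[mask] if self.year is not None else None
        return PointPattern(ids, self.xy[mask], self.window, year)


@dataclass
class StudyDesign:
    """Nested sampling design: individual -> nest -> cluster -> site -> population.

    ``table`` has one row per individual with columns
    individual, nest, cluster, site, population. ``cluster`` may be NA (it is
    typically assigned later from the percolation analysis).
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = ["individual", "nest", "cluster", "site", "population"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["individual"].duplicated().any():
            dup = self.table.loc[self.table["individual"].duplicated(), "individual"]
            raise ValueError(f"duplicate individuals in design: {sorted(set(dup))}")

    def check_tree(self):
        """Raise if any unit has more than one parent (mapping is not a tree)."""
        pairs = [("nest", "cluster"), ("cluster", "site"), ("site", "population")]
        for child, parent in pairs:
            sub = self.table[[child, parent]].dropna().drop_duplicates()
            counts = sub.groupby(child)[parent].nunique()
            bad = counts[counts > 1]
            if len(bad):
                raise ValueError(
                    f"design is not a tree: {child} {list(bad.index)} map to "
                    f"multiple {parent}s"
                )

    def with_clusters(self, labels: dict) -> "StudyDesign":
        """Return a design with the ``cluster`` column replaced from a
        nest -> cluster mapping (e.g. a percolation ClusterAssignment)."""
        table = self.table.copy()
        table["cluster"] = table["nest"].map(labels)
        return StudyDesign(table)


@dataclass
class ValidationReport:
    """Advisory cross-checks between panel, coordinates, and design."""

    orphan_nests: list = field(default_factory=list)
    unlabeled_individuals: list = field(default_factory=list)
    sparse_loci: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.orphan_nests or self.unlabeled_individuals or self.sparse_loci)


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

def _parse_fused(token: str, width: int, lineno: int) -> tuple:
    token = token.strip()
    if not token.isdigit() or len(token) != 2 * width:
        raise GenotypeParseError(
            f"line {lineno}: genotype token '{token}' is not {2 * width} digits"
        )
    return int(token[:width]), int(token[width:])


def read_genepop(path, allele_length: int = 3) -> GenotypePanel:
    """Read a Genepop file (title, locus names, POP blocks, fused alleles).

    Locus names may be one per line or comma-separated on a single line.
    Fused codes of all zeros mark a missing genotype. POP blocks become
    population labels ``pop_1``, ``pop_2``, ...
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError("empty file")
    header_end = None
    locus_names = []
    for i, line in enumerate(lines[1:], start=2):
        if line.strip().lower() == "pop":
            header_end = i
            break
        for nm in line.split(","):
            nm = nm.strip()
            if nm:
                locus_names.append(nm)
    loci = [Locus(nm, allele_length) for nm in locus_names]
    individuals, rows, pops = [], [], []
    if header_end is None:
        if not locus_names:
            raise GenotypeParseError("no locus names found")
        return GenotypePanel([], loci, np.zeros((0, len(loci), 2), dtype=np.int64))
    pop_idx = 0
    for lineno, line in enumerate(lines[header_end:], start=header_end + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_idx += 1
            continue
        if pop_idx == 0:
            pop_idx = 1
        if "," not in stripped:
            raise GenotypeParseError(f"line {lineno}: expected 'id , genotypes'")
        ind_id, rest = stripped.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"line {lineno}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        row = [
            _parse_fused(tok, allele_length, lineno) for tok in tokens
        ]
        individuals.append(ind_id.strip())
        rows.append(row)
        pops.append(f"pop_{pop_idx}")
    calls = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(loci), 2), dtype=np.int64)
    )
    labels = pd.DataFrame(
        {"population": pops}, index=pd.Index(individuals, name="id")
    )
    return GenotypePanel(individuals, loci, calls, labels)


def write_genepop(panel: GenotypePanel, path, title: str = "nestkin export"):
    """Write a panel as a Genepop file, one POP block per population label."""
    width = panel.loci[0].allele_length if panel.loci else 3
    pops = panel.labels["population"].fillna("pop_1")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for nm in panel.locus_names:
            fh.write(nm + "\n")
        for pop in pd.unique(pops):
            fh.write("POP\n")
            for i, ind in enumerate(panel.individuals):
                if pops.iloc[i] != pop:
                    continue
                toks = [
                    f"{a:0{width}d}{b:0{width}d}" for a, b in panel.calls[i]
                ]
                fh.write(f"{ind} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_coordinates(path, window: tuple = None) -> PointPattern:
    """Read nest coordinates from CSV with columns id,x,y[,year] (meters).

    Values that look like geographic lat/long (|x| <= 180 and |y| <= 90) are
    rejected: the spatial statistics require projected planar meters.
    The window defaults to the bounding box of the points.
    """
    df = pd.read_csv(path)
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinates CSV missing column '{col}'")
    if df["id"].duplicated().any():
        dup = sorted(set(df.loc[df["id"].duplicated(), "id"].astype(str)))
        raise ValueError(f"duplicate point ids: {dup}")
    x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
    if len(x) and (np.abs(x) <= 180).all() and (np.abs(y) <= 90).all():
        raise ValueError(
            "coordinates look like geographic lat/long; project to planar "
            "meters (e.g. UTM) before analysis"
        )
    if window is None:
        window = (x.min(), x.max(), y.min(), y.max())
        # degenerate bounding boxes (collinear points) get a 1 m margin
        if window[0] == window[1]:
            window = (window[0] - 0.5, window[1] + 0.5, window[2], window[3])
        if window[2] == window[3]:
            window = (window[0], window[1], window[2] - 0.5, window[3] + 0.5)
    year = df["year"].to_numpy() if "year" in df.columns else None
    return PointPattern(list(df["id"].astype(str)), np.column_stack([x, y]), window, year)


def read_design(path) -> StudyDesign:
    """Read a design CSV (individual,nest,cluster,site,population)."""
    df = pd.read_csv(path, dtype=str)
    return StudyDesign(df)


def read_genotypes_csv(path, allele_length: int = 3) -> GenotypePanel:
    """Read the wide CSV genotype dialect.

    Columns: id, population, site, nest, stage, then ``locus.a1``/``locus.a2``
    pairs (or fused ``locus`` columns of 2*allele_length digits). 0 = missing.
    """
    df = pd.read_csv(path, dtype=str).fillna("0")
    meta = [c for c in ("id", "population", "site", "nest", "stage") if c in df.columns]
    if "id" not in meta:
        raise ValueError("genotype CSV missing 'id' column")
    geno_cols = [c for c in df.columns if c not in meta]
    paired = {}
    for c in geno_cols:
        m = re.match(r"^(.*)\.(a1|a2)$", c)
        if m:
            paired.setdefault(m.group(1), {})[m.group(2)] = c
        else:
            paired[c] = {"fused": c}
    loci, cols = [], []
    for nm, d in paired.items():
        loci.append(Locus(nm, allele_length))
        cols.append(d)
    n = len(df)
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, d in enumerate(cols):
        if "fused" in d:
            for i, tok in enumerate(df[d["fused"]]):
                tok = tok.strip()
                if tok in ("0", ""):
                    continue
                calls[i, j] = _parse_fused(tok, allele_length, i + 2)
        else:
            calls[:, j, 0] = df[d["a1"]].astype(int)
            calls[:, j, 1] = df[d["a2"]].astype(int)
    labels = pd.DataFrame(index=pd.Index(df["id"], name="id"))
    rename = {"site": "nesting_site", "stage": "life_stage"}
    for c in meta:
        if c == "id":
            continue
        labels[rename.get(c, c)] = df[c].to_numpy()
    return GenotypePanel(list(df["id"]), loci, calls, labels)


def write_genotypes_csv(panel: GenotypePanel, path):
    """Write a panel in the wide CSV dialect (two columns per locus)."""
    out = {"id": panel.individuals}
    lab = panel.labels
    out["population"] = lab["population"].to_numpy()
    out["site"] = lab["nesting_site"].to_numpy()
    out["nest"] = lab["nest"].to_numpy()
    out["stage"] = lab["life_stage"].to_numpy()
    for j, loc in enumerate(panel.loci):
        out[f"{loc.name}.a1"] = panel.calls[:, j, 0]
        out[f"{loc.name}.a2"] = panel.calls[:, j, 1]
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation and subsetting
# ---------------------------------------------------------------------------

def validate_study(
    panel: GenotypePanel,
    pattern: PointPattern = None,
    design: StudyDesign = None,
    sparse_threshold: float = 0.5,
) -> ValidationReport:
    """Cross-check a study. Tree violations in the design are fatal
    (raise); everything else is advisory and listed in the report."""
    report = ValidationReport()
    if design is not None:
        design.check_tree()
        known = set(design.table["individual"])
        report.unlabeled_individuals = [
            i for i in panel.individuals if i not in known
        ]
        if pattern is not None:
            coords = set(pattern.ids)
            nests = design.table["nest"].dropna().unique()
            report.orphan_nests = sorted(str(n) for n in nests if str(n) not in coords)
    unlabeled = panel.labels["population"].isna()
    report.unlabeled_individuals = sorted(
        set(report.unlabeled_individuals)
        | set(np.asarray(panel.individuals)[unlabeled.to_numpy()])
    )
    if panel.n_individuals:
        miss = panel.missing_mask().mean(axis=0)
        report.sparse_loci = [
            panel.loci[j].name for j in range(panel.n_loci) if miss[j] > sparse_threshold
        ]
    return report


def one_hatchling_per_nest(panel: GenotypePanel) -> GenotypePanel:
    """Subset to one hatchling per nest (first by sorted id), keeping adults.

    The deterministic sorted-id rule makes reduced datasets reproducible.
    """
    lab = panel.labels
    keep = []
    seen_nests = set()
    for ind in sorted(panel.individuals):
        stage = lab.loc[ind, "life_stage"]
        nest = lab.loc[ind, "nest"]
        if stage == "hatchling" and not pd.isna(nest):
            if nest in seen_nests:
                continue
            seen_nests.add(nest)
        keep.append(ind)
    order = [i for i in panel.individuals if i in set(keep)]
    return panel.subset_individuals(order)
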