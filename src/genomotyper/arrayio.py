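"""Readers and writers for the tabular formats used across the pipeline.

The canonical intensity format is a long (tidy) TSV with one spot per row::

    probe_id  strain  replicate  log2_ratio  [test_signal  ref_signal  background]

Normalized log2(test/reference) ratios are the input boundary: upstream
scanner/feature-extraction normalization is assumed done.  A wide,
feature-extraction-like layout (one column per strain/replicate pair named
``<strain>|<replicate>``) is accepted behind ``fmt="wide"``.

Phenotype fixtures transcribing the published strain tables (coccolith
status; the 16x9 virus-lysis matrix) ship with the package and are exposed
through :func:`load_trait_fixture`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .trees import Node, to_newick

_MANDATORY_COLS = ["probe_id", "strain", "replicate", "log2_ratio"]
_RAW_COLS = ["test_signal", "ref_signal", "background"]


@dataclass
class LogRatioTensor:
    """Per-probe, per-strain, per-replicate normalized log2(test/reference) ratios.

    ``values`` has shape (probes, strains, replicates) with NaN marking
    missing spots.  ``raw`` optionally carries per-spot channel signals and
    background estimates (needed only for the self-self background QC).
    """

    probe_ids: list[str]
    strains: list[str]
    values: np.ndarray
    reference: str | None = None
    outgroups: list[str] = field(default_factory=list)
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (len(self.probe_ids), len(self.strains)):
            raise ValueError("values shape does not match probe/strain labels")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("probe_ids are not unique")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def strain_index(self, strain: str) -> int:
        return self.strains.index(strain)

    def subset_probes(self, keep: np.ndarray) -> "LogRatioTensor":
        """Restrict to a boolean probe mask (or an index array)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        ids = [self.probe_ids[i] for i in idx]
        raw = None
        if self.raw is not None:
            raw = self.raw[self.raw["probe_id"].isin(set(ids))].reset_index(drop=True)
        return LogRatioTensor(ids, list(self.strains), self.values[idx],
                              self.reference, list(self.outgroups), raw)


@dataclass
class TraitTable:
    """Two-group phenotype assignment: strain -> 'A', 'B' or 'excluded'."""

    labels: dict[str, str]
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"A", "B", "excluded"}
        if bad:
            raise ConfigError(f"invalid trait labels: {sorted(bad)}")

    def group(self, label: str) -> list[str]:
        return [s for s, v in self.labels.items() if v == label]

    def validate_groups(self) -> None:
        if not self.group("A") or not self.group("B"):
            raise ConfigError(
                f"trait '{self.trait_name}' needs at least one strain in each group "
                f"(A={len(self.group('A'))}, B={len(self.group('B'))})")


def _read_tsv_checked(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _to_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col].replace({"": np.nan, "NA": np.nan}), errors="coerce")
    raw_nonempty = ~df[col].isin(["", "NA", "nan"])
    bad = vals.isna() & raw_nonempty
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
        raise FormatError(
            f"{path}: malformed numeric value(s) in column '{col}' at line(s) {lines}")
    return vals.to_numpy(dtype=float)


def read_intensity_table(path, *, fmt: str = "long", reference: str | None = None,
                         outgroups: list[str] | None = None) -> LogRatioTensor:
    """Read an intensity table into a :class:`LogRatioTensor`.

    Probe and strain order follow first occurrence in the file.  Duplicate
    (probe, strain, replicate) triples and malformed numeric cells are
    reported with their line numbers.
    """
    if fmt == "wide":
        return _read_wide(path, reference=reference, outgroups=outgroups)
    if fmt != "long":
        raise ConfigError(f"unknown intensity format {fmt!r}")
    df = _read_tsv_checked(path, _MANDATORY_COLS)
    dup = df.duplicated(subset=["probe_id", "strain", "replicate"], keep="first")
    if dup.any():
        line = int(df.index[dup][0]) + 2
        key = tuple(df.loc[df.index[dup][0], ["probe_id", "strain", "replicate"]])
        raise FormatError(f"{path}: duplicate (probe,strain,replicate) {key} at line {line}")

    ratios = _to_float(df, "log2_ratio", path)
    probes = list(pd.unique(df["probe_id"]))
    strains = list(pd.unique(df["strain"]))
    reps = list(pd.unique(df["replicate"]))
    g = pd.Categorical(df["probe_id"], categories=probes).codes
    s = pd.Categorical(df["strain"], categories=strains).codes
    r = pd.Categorical(df["replicate"], categories=reps).codes
    values = np.full((len(probes), len(strains), len(reps)), np.nan)
    values[g, s, r] = ratios

    raw = None
    if all(c in df.columns for c in _RAW_COLS):
        raw = df[["probe_id", "strain", "replicate"] + _RAW_COLS].copy()
        for c in _RAW_COLS:
            raw[c] = _to_float(raw, c, path)
    return LogRatioTensor(probes, strains, values, reference, outgroups or [], raw)


def _read_wide(path, *, reference=None, outgroups=None) -> LogRatioTensor:
    df = _read_tsv_checked(path, ["probe_id"])
    cols = [c for c in df.columns if c != "probe_id"]
    pairs = []
    for c in cols:
        if "|" not in c:
            raise FormatError(f"{path}: wide column {c!r} is not '<strain>|<replicate>'")
        pairs.append(tuple(c.split("|", 1)))
    strains = list(dict.fromkeys(p[0] for p in pairs))
    reps = list(dict.fromkeys(p[1] for p in pairs))
    probes = list(df["probe_id"])
    if len(set(probes)) != len(probes):
        raise FormatError(f"{path}: duplicate probe_id rows")
    values = np.full((len(probes), len(strains), len(reps)), np.nan)
    for c, (st, rp) in zip(cols, pairs):
        values[:, strains.index(st), reps.index(rp)] = _to_float(df, c, path)
    return LogRatioTensor(probes, strains, values, reference, outgroups or [])


def write_intensity_table(tensor: LogRatioTensor, path) -> None:
    """Write the canonical long TSV; deterministic bytes for identical input."""
    rows = []
    has_raw = tensor.raw is not None
    raw_lookup = {}
    if has_raw:
        for rec in tensor.raw.itertuples(index=False):
            raw_lookup[(rec.probe_id, rec.strain, str(rec.replicate))] = (
                rec.test_signal, rec.ref_signal, rec.background)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = _MANDATORY_COLS + (_RAW_COLS if has_raw else [])
        fh.write("\t".join(cols) + "\n")
        for gi, probe in enumerate(tensor.probe_ids):
            for si, strain in enumerate(tensor.strains):
                for ri in range(tensor.n_replicates):
                    v = tensor.values[gi, si, ri]
                    if np.isnan(v):
                        continue
                    row = [probe, strain, str(ri + 1), format(v, ".12g")]
                    if has_raw:
                        t, r, b = raw_lookup.get((probe, strain, str(ri + 1)),
                                                 (np.nan, np.nan, np.nan))
                        row += [format(t, ".12g"), format(r, ".12g"), format(b, ".12g")]
                    fh.write("\t".join(row) + "\n")
    return None


def load_strain_aliases() -> dict[str, str]:
    ref = importlib.resources.files("genomotyper.data") / "strain_aliases.tsv"
    df = pd.read_csv(ref, sep="\t", dtype=str)
    return dict(zip(df["alias"], df["canonical"]))


def normalize_strain_name(name: str) -> str:
    """Map printed strain-name variants (e.g. '12-1 ( = CCMP371)') to canonical ids."""
    name = name.strip()
    return load_strain_aliases().get(name, name)


def load_trait_fixture(name: str, *, min_lysed: int = 1) -> TraitTable:
    """Load a packaged phenotype fixture as a two-group trait table.

    ``"coccoliths"``: calcifying (Y) strains -> group A, non-calcifying -> B.
    ``"virus_susceptibility"``: a strain joins the susceptible group A when it
    is lysed by at least ``min_lysed`` of the nine EhV virus strains (the
    published record gives the full lysis matrix but no explicit grouping
    rule, so the rule is a parameter; default 1).
    """
    base = importlib.resources.files("genomotyper.data")
    if name == "coccoliths":
        df = pd.read_csv(base / "coccoliths.tsv", sep="\t", dtype=str)
        labels = {row.strain: ("A" if row.coccoliths == "Y" else "B")
                  for row in df.itertuples(index=False)}
        return TraitTable(labels, trait_name="coccoliths")
    if name == "virus_susceptibility":
        df = pd.read_csv(base / "virus_lysis.tsv", sep="\t", dtype=str).set_index("strain")
        n_plus = (df == "+").sum(axis=1)
        labels = {strain: ("A" if n >= min_lysed else "B") for strain, n in n_plus.items()}
        return TraitTable(labels, trait_name="virus_susceptibility")
    raise ConfigError(f"unknown trait fixture {name!r}")


def load_lysis_matrix() -> pd.DataFrame:
    """The transcribed 16-strain x 9-virus lysis matrix ('+'/'-')."""
    base = importlib.resources.files("genomotyper.data")
    return pd.read_csv(base / "virus_lysis.tsv", sep="\t", dtype=str).set_index("strain")


def read_trait_table(path, trait_name: str = "trait") -> TraitTable:
    """Generic two-column TSV (strain, group with values A/B/excluded)."""
    df = _read_tsv_checked(path, ["strain", "group"])
    return TraitTable(dict(zip(df["strain"], df["group"])), trait_name=trait_name)


def write_trait_table(traits: TraitTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("strain\tgroup\n")
        for strain, label in traits.labels.items():
            fh.write(f"{strain}\t{label}\n")


def write_newick(tree: Node, path) -> None:
    """Write a tree (supports as internal-node labels) as standard Newick."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(to_newick(tree) + "\n")


def write_matrix(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    """Write a genes-as-rows (or square) matrix TSV with a header row."""
    df.to_csv(path, sep="\t", float_format=float_format, lineterminator="\n")
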