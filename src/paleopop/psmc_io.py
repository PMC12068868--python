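"""Readers and writers for the formats the pipeline touches.

The one hand-written parser here is for the ``psmc`` program's output
text: a sequence of blocks, one per EM iteration ("round"), each opened
by an ``RD`` line, closed by ``//``, and carrying ``TR`` (theta0, rho0),
``MT`` (upper coalescent time bound), ``PA`` (the atomic time-interval
pattern) and ``RS`` lines (one per time segment: index, coalescent time
t_k, relative size lambda_k, plus trailing columns we ignore).  Newick
trees go through dendropy and tabular files through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

ALLOWED_GROUPS = ("migrant", "resident")

#: line codes psmc emits that carry nothing this pipeline consumes
_IGNORED_CODES = frozenset({"LK", "QD", "RI", "MM", "DC", "TC", "MR", "C", "IT"})


class PsmcParseError(ValueError):
    """Raised when a PSMC output file cannot be parsed."""


@dataclass
class PsmcRound:
    """One EM iteration of a PSMC run.

    ``segments`` is the piecewise-constant history in coalescent units:
    ordered pairs (t_k, lambda_k) with t_0 = 0, t strictly increasing and
    lambda_k > 0.  ``theta0`` is the scaled mutation rate per bin and sets
    the baseline population size when converting to natural units.
    """

    round_index: int
    theta0: float
    rho0: float
    max_t_coal: float
    segments: list[tuple[float, float]]
    pattern: str = ""

    def __post_init__(self) -> None:
        if self.theta0 <= 0:
            raise ValueError(f"theta0 must be > 0, got {self.theta0}")
        if len(self.segments) < 2:
            raise ValueError("a PSMC round needs at least 2 RS segments")
        ts = [t for t, _ in self.segments]
        if ts[0] != 0.0:
            raise ValueError(f"first segment time must be 0, got {ts[0]}")
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValueError(f"segment times must strictly increase ({a} -> {b})")
        for _, lam in self.segments:
            if lam <= 0:
                raise ValueError(f"lambda_k must be > 0, got {lam}")


@dataclass
class PsmcRaw:
    """All rounds of one PSMC output file, in file order."""

    rounds: list[PsmcRound]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("PsmcRaw requires at least one round")

    def last_round(self) -> PsmcRound:
        return max(self.rounds, key=lambda r: r.round_index)


def last_round(p: PsmcRaw) -> PsmcRound:
    """The round with the largest round index (the converged EM iterate)."""
    return p.last_round()


def _parse_floats(parts: list[str], lineno: int, code: str) -> list[float]:
    try:
        return [float(x) for x in parts]
    except ValueError as exc:
        raise PsmcParseError(f"line {lineno}: malformed {code} numeric field: {exc}") from exc


def parse_psmc(text: str, source_label: str = "") -> PsmcRaw:
    """Parse PSMC output text into all of its rounds.

    Unknown line codes are skipped.  Only the 2nd and 3rd whitespace
    fields of each ``RS`` line (t_k and lambda_k) are consumed; trailing
    columns are ignored for forward compatibility.

    Raises
    ------
    PsmcParseError
        On malformed TR/RS numeric fields (naming the line number) or
        when the text contains no complete block.
    """
    rounds: list[PsmcRound] = []
    cur: dict | None = None

    def _finish(block: dict, lineno: int) -> None:
        try:
            rounds.append(
                PsmcRound(
                    round_index=block["index"],
                    theta0=block.get("theta0", -1.0),
                    rho0=block.get("rho0", 0.0),
                    max_t_coal=block.get("max_t", 0.0),
                    segments=block.get("segments", []),
                    pattern=block.get("pattern", ""),
                )
            )
        except ValueError as exc:
            raise PsmcParseError(f"block ending at line {lineno}: {exc}") from exc

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("//"):
            if cur is not None:
                _finish(cur, lineno)
                cur = None
            continue
        parts = line.split()
        code = parts[0]
        if code == "RD":
            if cur is not None:  # unterminated previous block
                _finish(cur, lineno)
            idx = int(_parse_floats(parts[1:2], lineno, "RD")[0]) if len(parts) > 1 else len(rounds)
            cur = {"index": idx, "segments": []}
        elif cur is None:
            continue  # preamble outside any block
        elif code == "TR":
            if len(parts) < 3:
                raise PsmcParseError(f"line {lineno}: TR needs two numeric fields")
            cur["theta0"], cur["rho0"] = _parse_floats(parts[1:3], lineno, "TR")
        elif code == "MT":
            cur["max_t"] = _parse_floats(parts[1:2], lineno, "MT")[0]
        elif code == "PA":
            cur["pattern"] = " ".join(parts[1:])
        elif code == "RS":
            if len(parts) < 4:
                raise PsmcParseError(f"line {lineno}: RS needs at least 3 numeric fields")
            t_k, lam = _parse_floats(parts[2:4], lineno, "RS")
            cur["segments"].append((t_k, lam))
        # anything else (LK, QD, RI, MM, DC, ...) is skipped

    if cur is not None:
        _finish(cur, lineno)
    if not rounds:
        raise PsmcParseError("no PSMC blocks found in input")
    return PsmcRaw(rounds=rounds, source_label=source_label)


def read_psmc(path: str | Path, source_label: str | None = None) -> PsmcRaw:
    path = Path(path)
    return parse_psmc(path.read_text(), source_label or path.stem)


# ---------------------------------------------------------------------------
# trees


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Trees are force-rooted as written; duplicate tip labels are an error.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"could not parse Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# manifests and tables


@dataclass
class ManifestEntry:
    taxon_id: str
    group: str
    psmc_path: str
    replicate_paths: list[str] = field(default_factory=list)


@dataclass
class SampleManifest:
    """Assignment of each lineage to a group plus its PSMC file(s).

    The TSV layout is ``taxon_id  group  psmc_path  [replicates]`` where
    ``replicates`` is a semicolon-separated list of bootstrap-replicate
    PSMC files; replicate files are associated here explicitly, never by
    filename globbing.
    """

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.taxon_id for e in self.entries]
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        if dupes:
            raise ValueError(f"duplicate taxon_id in manifest: {dupes}")
        for e in self.entries:
            if e.group not in ALLOWED_GROUPS:
                raise ValueError(
                    f"unknown group {e.group!r} for {e.taxon_id}; allowed: {list(ALLOWED_GROUPS)}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return [e.taxon_id for e in self.entries]


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"taxon_id", "group", "psmc_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing required column(s): {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        reps = []
        if "replicates" in df.columns and row["replicates"]:
            reps = [r for r in str(row["replicates"]).split(";") if r]
        entries.append(
            ManifestEntry(
                taxon_id=row["taxon_id"],
                group=row["group"],
                psmc_path=row["psmc_path"],
                replicate_paths=reps,
            )
        )
    return SampleManifest(entries=entries)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    rows = [
        {
            "taxon_id": e.taxon_id,
            "group": e.group,
            "psmc_path": e.psmc_path,
            "replicates": ";".join(e.replicate_paths),
        }
        for e in manifest.entries
    ]
    write_table(rows, path)


def write_table(rows, path: str | Path) -> None:
    """Write rows (list of dicts or a DataFrame) as a UTF-8 TSV.

    Tab-delimited, "." decimal, no thousands separators; float columns
    are rendered with %.10g so repeated runs are byte-identical.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"table {path} has no data rows")
    return df
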