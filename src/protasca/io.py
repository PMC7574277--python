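"""Domain containers and readers/writers for the tabular and ontology inputs.

The pipeline consumes four kinds of input:

* a protein x sample spectral-count table with protein lengths (or a
  precomputed NSAF abundance table; the Abacus label-free quantification
  output is the reference dialect),
* a sample design table mapping each LC-MS/MS run to its time point
  (days post-fertilization), rearing temperature and technical-replicate id,
* a protein -> GO annotation table plus an OBO ontology and an optional
  GO-Slim accession list,
* a run-level provenance record tying outputs back to configuration and seeds.

All tables are tab-separated UTF-8 with a header row. Output tables carry a
``#`` comment line with the package version and run-record id so any
intermediate can be traced to one run.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from . import __version__

SCALE_TAGS = ("counts", "nsaf", "adjusted_nsaf", "log2", "autoscaled")

#: ontology edge types followed during ancestor propagation
DEFAULT_RELATIONS = ("is_a", "part_of")


class ProtascaError(ValueError):
    """Base class for user-facing input and contract errors."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpectralCountTable:
    """Protein x sample spectral counts with per-protein sequence lengths.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, proteins as rows (index = protein id),
        samples as columns.
    lengths
        Protein sequence lengths in amino-acid residues, indexed like
        ``counts``; strictly positive.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise ProtascaError(f"duplicate protein ids: {dups}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = sorted(self.lengths.index[self.lengths.isna()])
            raise ProtascaError(f"proteins without a length: {missing}")
        if (self.lengths <= 0).any():
            bad = sorted(self.lengths.index[self.lengths <= 0])
            raise ProtascaError(f"non-positive protein lengths: {bad}")
        if (self.counts.to_numpy() < 0).any():
            raise ProtascaError("spectral counts must be non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class AbundanceMatrix:
    """A quantitative protein x sample matrix with an explicit scale tag.

    ``scale_tag`` records where the matrix sits in the preprocessing chain:
    ``nsaf`` (column-stochastic), ``adjusted_nsaf`` (NSAF times an export
    scale), ``log2``, or ``autoscaled`` (rows standardized to mean 0, sd 1).
    ``flagged_rows`` lists proteins whose rows could not be autoscaled
    (zero variance) and were left at zero.
    """

    values: pd.DataFrame
    scale_tag: str
    flagged_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ProtascaError(
                f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}"
            )
        if self.values.isna().any().any():
            raise ProtascaError("abundance matrix contains missing cells")
        if self.values.index.duplicated().any():
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ProtascaError(f"duplicate protein ids: {dups}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, scale_tag: str,
                    flagged_rows: tuple[str, ...] = ()) -> "AbundanceMatrix":
        return AbundanceMatrix(values=values, scale_tag=scale_tag,
                               flagged_rows=flagged_rows)


REQUIRED_DESIGN_COLUMNS = ("sample_id", "time_dpf", "temperature_c", "replicate_id")


@dataclass
class SampleDesign:
    """Per-sample factor levels: time (dpf), temperature (degrees C), replicate id.

    The (time, temperature, replicate) triple must be unique per sample.
    ``unbalanced_samples`` lists samples sitting in factor-level cells that do
    not share the modal replication (e.g. a single extra sample at a third
    temperature), which makes a two-factor decomposition non-orthogonal.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ProtascaError(f"design table missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["time_dpf"] = t["time_dpf"].astype(int)
        t["temperature_c"] = t["temperature_c"].astype(float)
        t["replicate_id"] = t["replicate_id"].astype(str)
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise ProtascaError(f"duplicate sample ids in design: {dups}")
        triple = t[["time_dpf", "temperature_c", "replicate_id"]]
        if triple.duplicated().any():
            dups = triple[triple.duplicated()].to_records(index=False).tolist()
            raise ProtascaError(
                f"duplicated (time_dpf, temperature_c, replicate_id) triples: {dups}"
            )
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def time_levels(self) -> list[int]:
        return sorted(self.table["time_dpf"].unique())

    @property
    def temperature_levels(self) -> list[float]:
        return sorted(self.table["temperature_c"].unique())

    def factor_labels(self, factor: str) -> pd.Series:
        """Level label per sample for ``time``, ``temperature`` or ``interaction``."""
        if factor == "time":
            return self.table["time_dpf"]
        if factor == "temperature":
            return self.table["temperature_c"]
        if factor == "interaction":
            return (self.table["time_dpf"].astype(str) + "/"
                    + self.table["temperature_c"].astype(str))
        raise ProtascaError(f"unknown factor {factor!r}")

    @property
    def unbalanced_samples(self) -> list[str]:
        """Samples in (time, temperature) cells whose size differs from the mode."""
        cells = self.table.groupby(["time_dpf", "temperature_c"])["sample_id"]
        sizes = cells.size()
        modal = sizes.mode().iloc[0]
        # a temperature (or time) level appearing in only one cell also breaks
        # the crossed layout even if its cell size matches the mode
        bad: set[str] = set()
        for (t, g), ids in cells:
            n_cells_temp = (self.table["temperature_c"] == g).sum()
            n_cells_time = (self.table["time_dpf"] == t).sum()
            if sizes[(t, g)] != modal or n_cells_temp == sizes[(t, g)] \
                    or n_cells_time == sizes[(t, g)]:
                bad.update(ids)
        return sorted(bad)

    @property
    def is_balanced(self) -> bool:
        return not self.unbalanced_samples

    def subset(self, sample_ids: Iterable[str]) -> "SampleDesign":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return SampleDesign(self.table.loc[keep].reset_index(drop=True))


@dataclass
class GoAnnotationMap:
    """Protein -> GO annotations over an ontology DAG.

    ``annotations`` maps each protein id to the set of GO accessions it is
    annotated to *after* true-path propagation to every ancestor reachable
    along the configured relations (``is_a``/``part_of`` by default).
    ``direct_annotations`` holds the pre-propagation sets. ``ontology`` is the
    obonet graph (edges point child -> parent). ``slim_subset`` is an optional
    reduced vocabulary used for rollups.
    """

    annotations: dict[str, frozenset[str]]
    direct_annotations: dict[str, frozenset[str]]
    ontology: nx.MultiDiGraph
    relations: tuple[str, ...] = DEFAULT_RELATIONS
    slim_subset: frozenset[str] = frozenset()
    dropped_terms: dict[str, int] = field(default_factory=dict)

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestors of ``term`` along the configured relations (term excluded)."""
        return _ancestors(self.ontology, term, self.relations)

    def namespace(self, term: str) -> str | None:
        return self.ontology.nodes[term].get("namespace") if term in self.ontology else None


def _relation_subgraph(graph: nx.MultiDiGraph,
                       relations: tuple[str, ...]) -> nx.DiGraph:
    sub = nx.DiGraph()
    sub.add_nodes_from(graph.nodes)
    for u, v, key in graph.edges(keys=True):
        if key in relations:
            sub.add_edge(u, v)
    return sub


def _ancestors(graph: nx.MultiDiGraph, term: str,
               relations: tuple[str, ...]) -> frozenset[str]:
    if term not in graph:
        raise ProtascaError(f"term {term!r} not in ontology")
    cache = graph.graph.setdefault("_protasca_ancestors", {})
    if relations not in cache:
        sub = _relation_subgraph(graph, relations)
        # obonet edges point child -> parent, so ancestors are nx descendants
        cache[relations] = {n: frozenset(nx.descendants(sub, n))
                            for n in graph.nodes}
    return cache[relations][term]


@dataclass
class RunRecord:
    """Provenance for one pipeline run: config, seeds, version, checksums."""

    run_id: str
    config: dict
    seed: int | None = None
    software_version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    checksums: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.notes.append(message)

    def record_file(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.checksums[str(Path(path).name)] = digest

    def to_json(self, path: str | Path) -> None:
        payload = {
            "run_id": self.run_id,
            "config": self.config,
            "seed": self.seed,
            "software_version": self.software_version,
            "created": self.created,
            "checksums": self.checksums,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

#: default column patterns for the Abacus label-free quantification dialect;
#: Abacus headers vary across runs, so these are overridable
ABACUS_PATTERNS = {
    "protein_id": r"^PROTID$",
    "length": r"^PROTLEN$",
    "sample_value": r"^(?P<sample>.+)_ADJNSAF$",
}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def read_abundance_table(
    path: str | Path,
    dialect: str = "plain",
    patterns: Mapping[str, str] | None = None,
) -> SpectralCountTable | AbundanceMatrix:
    """Read a protein quantification table.

    ``plain`` dialect: first column ``protein_id``, optional ``length`` column,
    remaining columns one per sample. With a ``length`` column and
    integer-valued cells the result is a :class:`SpectralCountTable`;
    otherwise an :class:`AbundanceMatrix` tagged ``nsaf``.

    ``abacus`` dialect: columns are matched by regular-expression patterns
    (default: ``PROTID``, ``PROTLEN``, ``<sample>_ADJNSAF``) and the adjusted
    NSAF columns become an :class:`AbundanceMatrix` tagged ``adjusted_nsaf``.
    Input protein order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_tsv(path)
    if dialect == "abacus":
        pats = dict(ABACUS_PATTERNS)
        if patterns:
            pats.update(patterns)
        id_cols = [c for c in df.columns if re.match(pats["protein_id"], c)]
        if not id_cols:
            raise ProtascaError("abacus table: no protein id column matched")
        sample_map = {}
        for c in df.columns:
            m = re.match(pats["sample_value"], c)
            if m:
                sample_map[c] = m.group("sample")
        if not sample_map:
            raise ProtascaError("abacus table: no adjusted-NSAF columns matched")
        values = df.set_index(df[id_cols[0]].astype(str))[list(sample_map)]
        values.columns = [sample_map[c] for c in values.columns]
        values.index.name = "protein_id"
        _check_numeric(values, path)
        return AbundanceMatrix(values=values.astype(float), scale_tag="adjusted_nsaf")
    if dialect != "plain":
        raise ProtascaError(f"unknown dialect {dialect!r}")

    first = df.columns[0]
    df = df.set_index(df[first].astype(str)).drop(columns=[first])
    df.index.name = "protein_id"
    has_length = "length" in df.columns
    if has_length:
        lengths = pd.to_numeric(df["length"], errors="coerce")
        data = df.drop(columns=["length"])
    else:
        lengths = None
        data = df
    _check_numeric(data, path)
    data = data.astype(float)
    is_integral = (data.round() == data).all().all()
    if lengths is not None and is_integral:
        return SpectralCountTable(counts=data.astype(int), lengths=lengths.astype(int))
    if lengths is None and is_integral and (data.to_numpy() >= 0).all() \
            and data.to_numpy().max() > 1.5:
        raise ProtascaError(
            f"{path.name}: table looks like spectral counts but has no 'length' "
            "column; NSAF needs protein lengths")
    return AbundanceMatrix(values=data, scale_tag="nsaf")


def _check_numeric(df: pd.DataFrame, path: Path) -> None:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna()
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ProtascaError(f"{path.name}: non-numeric cell at row {row!r}, "
                            f"column {col!r}")


def write_abundance_table(
    obj: SpectralCountTable | AbundanceMatrix,
    path: str | Path,
    run_record: RunRecord | None = None,
) -> None:
    """Write a table in the plain dialect (round-trips via read_abundance_table)."""
    path = Path(path)
    if isinstance(obj, SpectralCountTable):
        out = obj.counts.copy()
        out.insert(0, "length", obj.lengths)
    else:
        out = obj.values
    with open(path, "w") as fh:
        fh.write(_header_comment(run_record))
        out.to_csv(fh, sep="\t", index_label="protein_id",
                   float_format="%.17g")
    if run_record is not None:
        run_record.record_file(path)


def _header_comment(run_record: RunRecord | None) -> str:
    rid = run_record.run_id if run_record else "adhoc"
    return f"# protasca {__version__} run={rid}\n"


def read_design(path: str | Path,
                run_record: RunRecord | None = None) -> SampleDesign:
    """Read and validate a sample design table.

    Requires columns ``sample_id, time_dpf, temperature_c, replicate_id``.
    Samples in cells that break the crossed factorial layout (for instance a
    lone pre-treatment sample at a third temperature) are accepted but listed
    in ``SampleDesign.unbalanced_samples`` and logged to the run record.
    """
    df = _read_tsv(Path(path))
    design = SampleDesign(df)
    if run_record is not None:
        run_record.log(
            f"design: {len(design.sample_ids)} samples, "
            f"time levels {design.time_levels}, "
            f"temperature levels {design.temperature_levels}")
        if design.unbalanced_samples:
            run_record.log(
                f"design: unbalanced samples {design.unbalanced_samples} "
                "(two-factor decomposition will warn)")
    return design


def write_design(design: SampleDesign, path: str | Path,
                 run_record: RunRecord | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(run_record))
        design.table.to_csv(fh, sep="\t", index=False)
    if run_record is not None:
        run_record.record_file(path)


def read_ontology(
    obo_path: str | Path,
    annotation_path: str | Path,
    slim_path: str | Path | None = None,
    relations: tuple[str, ...] = DEFAULT_RELATIONS,
    run_record: RunRecord | None = None,
) -> GoAnnotationMap:
    """Read an OBO ontology plus a protein -> GO annotation table.

    The annotation table is TSV with columns ``protein_id`` and ``go_terms``
    (semicolon- or comma-separated accessions). Annotations are propagated to
    every ancestor along ``relations`` (the GO true-path rule). Annotations to
    accessions absent from the graph (unknown or obsolete — obonet drops
    obsolete terms on read) are dropped with a warning and counted.
    """
    graph = obonet.read_obo(str(obo_path))
    if not nx.is_directed_acyclic_graph(_relation_subgraph(graph, relations)):
        raise ProtascaError("ontology graph is cyclic along " + "/".join(relations))

    ann_df = _read_tsv(Path(annotation_path))
    if "protein_id" not in ann_df.columns or "go_terms" not in ann_df.columns:
        raise ProtascaError("annotation table needs columns protein_id, go_terms")

    direct: dict[str, frozenset[str]] = {}
    dropped: dict[str, int] = {}
    for _, row in ann_df.iterrows():
        pid = str(row["protein_id"])
        raw = str(row["go_terms"]) if not pd.isna(row["go_terms"]) else ""
        terms = {t.strip() for t in re.split(r"[;,]", raw) if t.strip()}
        known = {t for t in terms if t in graph}
        for t in terms - known:
            dropped[t] = dropped.get(t, 0) + 1
        direct[pid] = direct.get(pid, frozenset()) | frozenset(known)
    if dropped:
        warnings.warn(
            f"dropped {sum(dropped.values())} annotation(s) to "
            f"{len(dropped)} unknown/obsolete term(s)", stacklevel=2)
        if run_record is not None:
            run_record.log(f"ontology: dropped annotations {dropped}")

    propagated = {
        pid: frozenset().union(*([terms] + [_ancestors(graph, t, relations)
                                            for t in terms])) if terms else frozenset()
        for pid, terms in direct.items()
    }

    slim: frozenset[str] = frozenset()
    if slim_path is not None:
        accs = [ln.strip() for ln in Path(slim_path).read_text().splitlines()
                if ln.strip() and not ln.startswith("#")]
        slim = frozenset(a for a in accs if a in graph)

    return GoAnnotationMap(annotations=propagated, direct_annotations=direct,
                           ontology=graph, relations=relations,
                           slim_subset=slim, dropped_terms=dropped)
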