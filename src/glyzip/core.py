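"""Domain types shared by all pipeline stages, plus readers/writers for the
standard file formats the pipeline touches (FASTA, UniProt entry XML,
tab-separated instance/feature tables).

Coordinate convention: all residue positions are 1-based and inclusive at
every public interface.  Conversion to 0-based indexing happens only inside
implementations.
"""

from __future__ import annotations

import enum
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_RESIDUE_SET = frozenset(STANDARD_RESIDUES)

#: Quantized TM-coverage levels for a 5-residue window.
COVERAGE_LEVELS = (0, 20, 40, 60, 80, 100)


class Evidence(str, enum.Enum):
    """Provenance status of a transmembrane annotation."""

    EXPERIMENTAL = "experimental"
    PREDICTED = "predicted"
    UNKNOWN = "unknown"


#: Default evidence filter: keep everything.
ALL_EVIDENCE = frozenset(Evidence)


@dataclass(frozen=True, order=True)
class TMFeature:
    """One annotated transmembrane span, 1-based inclusive on both ends."""

    start: int
    end: int
    evidence: Evidence = Evidence.UNKNOWN

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid TM feature bounds: start={self.start}, end={self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class ProteinRecord:
    """One protein entry: identifiers, organism context, sequence, TM features.

    ``pdb_id`` and ``chain_id`` are pass-through metadata.  Characters outside
    the 20 standard one-letter codes are permitted in ``sequence`` but exposed
    through :meth:`nonstandard_positions` so downstream stages can reject
    windows that touch them.
    """

    uniprot_id: str
    sequence: str
    organism: str = ""
    taxonomy: tuple[str, ...] = ()
    tm_features: list[TMFeature] = field(default_factory=list)
    pdb_id: str | None = None
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.uniprot_id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        self.taxonomy = tuple(self.taxonomy)
        for feat in self.tm_features:
            if feat.end > len(self.sequence):
                raise ValueError(
                    f"record {self.uniprot_id!r}: TM feature ({feat.start}, "
                    f"{feat.end}) exceeds sequence length {len(self.sequence)}"
                )
        # UniProt permits multiple, possibly overlapping spans; we only sort.
        self.tm_features = sorted(self.tm_features)

    def __len__(self) -> int:
        return len(self.sequence)

    def nonstandard_positions(self) -> list[int]:
        """1-based positions holding residues outside the standard 20."""
        return [
            i + 1
            for i, aa in enumerate(self.sequence)
            if aa not in STANDARD_RESIDUE_SET
        ]


@dataclass(frozen=True)
class MotifInstance:
    """One GXXXG occurrence inside a parent protein.

    ``start`` is the 1-based index of the first glycine; ``tm_coverage`` is
    20 times the number of the five motif residues lying inside any TM
    feature of the parent.
    """

    protein_ref: str
    motif: str
    start: int
    tm_coverage: int

    def __post_init__(self) -> None:
        if len(self.motif) != 5 or self.motif[0] != "G" or self.motif[4] != "G":
            raise ValueError(f"not a GXXXG 5-mer: {self.motif!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.tm_coverage not in COVERAGE_LEVELS:
            raise ValueError(
                f"tm_coverage must be one of {COVERAGE_LEVELS}, "
                f"got {self.tm_coverage}"
            )


class MotifCountTable:
    """Counts of unique motif strings for one labelled category."""

    def __init__(self, counts: Mapping[str, int], label: str = "") -> None:
        bad = {m: c for m, c in counts.items() if c < 1}
        if bad:
            raise ValueError(f"counts must be >= 1, offending entries: {bad}")
        self.counts: dict[str, int] = dict(counts)
        self.label = label

    @classmethod
    def from_motifs(cls, motifs: Iterable[str], label: str = "") -> "MotifCountTable":
        counts: dict[str, int] = {}
        for m in motifs:
            counts[m] = counts.get(m, 0) + 1
        return cls(counts, label=label)

    @classmethod
    def from_instances(
        cls, instances: Iterable[MotifInstance], label: str = ""
    ) -> "MotifCountTable":
        return cls.from_motifs((inst.motif for inst in instances), label=label)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def unique(self) -> int:
        return len(self.counts)

    def values(self) -> list[int]:
        return list(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifCountTable):
            return NotImplemented
        return self.counts == other.counts and self.label == other.label

    def __repr__(self) -> str:
        return (
            f"MotifCountTable(label={self.label!r}, unique={self.unique}, "
            f"total={self.total})"
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    The header token before the first whitespace becomes ``uniprot_id``;
    TM features are left empty.  Entries with empty sequences are collected
    and reported in a single error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    empty_headers: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            empty_headers.append(rec.description)
            continue
        records.append(ProteinRecord(uniprot_id=rec.id, sequence=seq))
    if empty_headers:
        raise ValueError(
            f"FASTA entries with empty sequences in {path}: {empty_headers}"
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.uniprot_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# UniProt entry XML
# ---------------------------------------------------------------------------

# ECO codes indicating direct experimental support; the sequence-analysis /
# automatic-annotation codes map to "predicted".
_EXPERIMENTAL_ECO = {"ECO:0000269", "ECO:0000305", "ECO:0007744"}
_PREDICTED_ECO = {"ECO:0000255", "ECO:0000256", "ECO:0000259", "ECO:0007829"}


def _local(tag: str) -> str:
    """Strip any XML namespace from a tag name."""
    return tag.rsplit("}", 1)[-1]


def _classify_evidence(eco_codes: set[str]) -> Evidence:
    if eco_codes & _EXPERIMENTAL_ECO:
        return Evidence.EXPERIMENTAL
    if eco_codes & _PREDICTED_ECO:
        return Evidence.PREDICTED
    return Evidence.UNKNOWN


def read_uniprot_xml(
    path: str | Path,
    allowed_evidence: frozenset[Evidence] | set[Evidence] = ALL_EVIDENCE,
) -> ProteinRecord:
    """Parse one locally stored UniProt entry XML into a :class:`ProteinRecord`.

    All ``<feature type="transmembrane region">`` elements are converted to
    :class:`TMFeature`; begin/end are read as 1-based inclusive.  Features
    whose evidence status is not in ``allowed_evidence`` are dropped (counted
    in the log); features lacking begin or end are skipped with a warning.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ValueError(f"malformed UniProt XML in {path}: {exc}") from exc
    root = tree.getroot()

    entry = root if _local(root.tag) == "entry" else None
    if entry is None:
        for child in root.iter():
            if _local(child.tag) == "entry":
                entry = child
                break
    if entry is None:
        raise ValueError(f"no <entry> element found in {path}")

    # entry-level evidence key -> ECO code
    eco_by_key: dict[str, str] = {}
    accession = None
    organism = ""
    taxonomy: list[str] = []
    sequence = None
    raw_features: list[tuple[int, int, Evidence]] = []
    n_dropped = 0

    for elem in entry.iter():
        tag = _local(elem.tag)
        if tag == "accession" and accession is None:
            accession = (elem.text or "").strip()
        elif tag == "evidence":
            key = elem.get("key")
            if key:
                eco_by_key[key] = elem.get("type", "")

    for elem in entry.iter():
        tag = _local(elem.tag)
        if tag == "organism":
            for sub in elem.iter():
                stag = _local(sub.tag)
                if stag == "name" and sub.get("type") == "scientific":
                    organism = (sub.text or "").strip()
                elif stag == "taxon":
                    taxonomy.append((sub.text or "").strip())
        elif tag == "sequence" and elem.text and elem.text.strip():
            sequence = "".join(elem.text.split())
        elif tag == "feature" and elem.get("type") == "transmembrane region":
            begin = end = None
            for sub in elem.iter():
                stag = _local(sub.tag)
                if stag == "begin" and sub.get("position"):
                    begin = int(sub.get("position"))
                elif stag == "end" and sub.get("position"):
                    end = int(sub.get("position"))
            if begin is None or end is None:
                logger.warning(
                    "%s: transmembrane feature lacking begin/end position skipped",
                    path,
                )
                continue
            keys = (elem.get("evidence") or "").split()
            eco = {eco_by_key.get(k, "") for k in keys}
            evidence = _classify_evidence({c for c in eco if c})
            if evidence not in allowed_evidence:
                n_dropped += 1
                continue
            raw_features.append((begin, end, evidence))

    if sequence is None:
        raise ValueError(f"no sequence element found in {path}")
    if accession is None:
        raise ValueError(f"no accession found in {path}")
    if n_dropped:
        logger.info(
            "%s: dropped %d TM feature(s) outside allowed evidence set",
            path,
            n_dropped,
        )

    return ProteinRecord(
        uniprot_id=accession,
        sequence=sequence,
        organism=organism,
        taxonomy=tuple(taxonomy),
        tm_features=[TMFeature(b, e, ev) for b, e, ev in raw_features],
    )


# ---------------------------------------------------------------------------
# TSV tables (tab separator, '.' decimal, mandatory header row)
# ---------------------------------------------------------------------------

_INSTANCE_COLUMNS = ["protein_ref", "motif", "start", "tm_coverage"]


def write_instance_table(
    instances: Sequence[MotifInstance], path: str | Path
) -> None:
    """Write motif instances as TSV with a mandatory header row."""
    df = pd.DataFrame(
        [
            (inst.protein_ref, inst.motif, inst.start, inst.tm_coverage)
            for inst in instances
        ],
        columns=_INSTANCE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_instance_table(path: str | Path) -> list[MotifInstance]:
    """Read a motif-instance TSV, validating every row.

    A ``tm_coverage`` outside {0, 20, 40, 60, 80, 100} (or any other field
    violating the :class:`MotifInstance` invariants) raises a validation
    error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_ref": str, "motif": str})
    missing = [c for c in _INSTANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"instance table {path} missing columns: {missing}")
    instances: list[MotifInstance] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            instances.append(
                MotifInstance(
                    protein_ref=str(row.protein_ref),
                    motif=str(row.motif),
                    start=int(row.start),
                    tm_coverage=int(row.tm_coverage),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid instance table row {i + 2} in {path}: {exc}") from exc
    return instances


def write_tm_features(
    features_by_protein: Mapping[str, Sequence[TMFeature]], path: str | Path
) -> None:
    rows = [
        (pid, f.start, f.end, f.evidence.value)
        for pid, feats in features_by_protein.items()
        for f in feats
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_tm_features(path: str | Path) -> dict[str, list[TMFeature]]:
    """Read a per-protein TM-feature TSV sidecar (protein_id, start, end, evidence)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TM feature table {path} missing columns: {sorted(missing)}")
    out: dict[str, list[TMFeature]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        ev = Evidence(getattr(row, "evidence", "unknown") or "unknown")
        try:
            feat = TMFeature(int(row.start), int(row.end), ev)
        except ValueError as exc:
            raise ValueError(f"invalid TM feature row {i + 2} in {path}: {exc}") from exc
        out.setdefault(str(row.protein_id), []).append(feat)
    return out


def attach_tm_features(
    records: Sequence[ProteinRecord],
    features_by_protein: Mapping[str, Sequence[TMFeature]],
) -> list[ProteinRecord]:
    """Return records with TM features from a sidecar table attached."""
    out = []
    for rec in records:
        feats = list(features_by_protein.get(rec.uniprot_id, []))
        out.append(
            ProteinRecord(
                uniprot_id=rec.uniprot_id,
                sequence=rec.sequence,
                organism=rec.organism,
                taxonomy=rec.taxonomy,
                tm_features=feats,
                pdb_id=rec.pdb_id,
                chain_id=rec.chain_id,
            )
        )
    return out


def write_protein_metadata(records: Sequence[ProteinRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.uniprot_id, r.organism, ";".join(r.taxonomy))
            for r in records
        ],
        columns=["protein_id", "organism", "taxonomy"],
    ).to_csv(path, sep="\t", index=False)


def read_protein_metadata(path: str | Path) -> dict[str, dict[str, object]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, dict[str, object]] = {}
    for row in df.itertuples(index=False):
        out[str(row.protein_id)] = {
            "organism": str(row.organism),
            "taxonomy": tuple(t for t in str(row.taxonomy).split(";") if t),
        }
    return out
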