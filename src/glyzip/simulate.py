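"""Synthetic proteome generator with ground truth.

Generates protein sequences with annotated TM segments, planted GXXXG
motifs whose type frequencies follow configurable heavy-tailed laws,
context-dependent X-position residue biases (hydrophobic inside TM,
polar/flexible outside), and planted redundancy (exact duplicates and
high-identity variant clusters), plus a manifest recording every planted
motif and cluster so downstream stages can be tested without downloads.

Strict-background mode draws background residues without glycine and keeps
planted windows G-free at the X positions and well separated, so an
exhaustive scan recovers *exactly* the planted motif set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    STANDARD_RESIDUES,
    Evidence,
    ProteinRecord,
    TMFeature,
    write_fasta,
    write_protein_metadata,
    write_tm_features,
)
from .redundancy import pairwise_identity

logger = logging.getLogger(__name__)

_AA = np.array(list(STANDARD_RESIDUES))
_G_INDEX = STANDARD_RESIDUES.index("G")


def _bias_vector(weights: Mapping[str, float], default: float = 0.01) -> np.ndarray:
    v = np.full(20, default, dtype=float)
    for aa, w in weights.items():
        v[STANDARD_RESIDUES.index(aa)] = w
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("residue weights must be non-negative and normalizable")
    return v / v.sum()

# Hydrophobic-leaning weights for membrane context; polar/flexible for the rest.
DEFAULT_TM_BIAS = _bias_vector(
    {"L": 0.30, "I": 0.13, "V": 0.13, "A": 0.11, "F": 0.09, "G": 0.06,
     "M": 0.06, "S": 0.03, "T": 0.03, "W": 0.03, "Y": 0.02, "C": 0.01},
    default=0.001,
)
DEFAULT_NONTM_BIAS = _bias_vector(
    {"G": 0.13, "S": 0.11, "E": 0.10, "K": 0.09, "A": 0.08, "P": 0.08,
     "D": 0.07, "R": 0.07, "T": 0.06, "Q": 0.05, "N": 0.05, "L": 0.02},
    default=0.004,
)


@dataclass(frozen=True)
class MotifLaw:
    """Heavy-tailed law for motif-type frequencies over a ranked type list."""

    kind: str = "power_law"  # power_law | lognormal | fixed_table
    alpha: float = 1.0       # power_law: P(rank r) propto r^-alpha
    mu: float = 1.0          # lognormal rank-weight parameters
    sigma: float = 1.0
    n_types: int = 300

    def rank_weights(self) -> np.ndarray:
        r = np.arange(1, self.n_types + 1, dtype=float)
        if self.kind == "power_law":
            w = r**-self.alpha
        elif self.kind == "lognormal":
            w = np.exp(-((np.log(r) - self.mu) ** 2) / (2 * self.sigma**2)) / r
        elif self.kind == "fixed_table":
            raise ValueError("fixed_table law has no rank weights")
        else:
            raise ValueError(f"unknown motif law kind: {self.kind}")
        return w / w.sum()


@dataclass(frozen=True)
class RedundancyPlan:
    n_duplicate_pairs: int = 4
    n_variant_clusters: int = 2
    variant_cluster_size: int = 3
    variant_identity: float = 96.0
    n_cross_organism_duplicates: int = 1

    def __post_init__(self) -> None:
        if not 95.0 <= self.variant_identity < 100.0:
            raise ValueError("variant_identity must be in [95, 100)")


@dataclass
class SimConfig:
    n_proteins: int = 320
    length_range: tuple[int, int] = (80, 400)
    tm_fraction: float = 0.55
    tm_segment_length: float = 21.0
    motifs_per_protein: float = 6.0
    tm_motif_fraction: float = 0.7  # planted-in-TM probability when TM exists
    motif_laws: dict[str, MotifLaw] = field(
        default_factory=lambda: {
            "tm": MotifLaw(kind="power_law", alpha=1.8, n_types=80),
            "non_tm": MotifLaw(kind="power_law", alpha=0.65, n_types=600),
            "shared": MotifLaw(kind="power_law", alpha=0.3, n_types=80),
        }
    )
    # fraction of planted motifs drawn from the "shared" pool, which is
    # planted into both structural contexts; shared_tm_prob controls how
    # often a shared-pool motif lands inside a TM segment (when one exists)
    shared_motif_fraction: float = 0.35
    shared_tm_prob: float = 0.2
    # additionally, types can be scattered into a rank window of every
    # context's own list: below the head (so dominant types stay exclusive)
    # but high enough to be drawn on both sides.  Off by default.
    n_shared_types: int = 0
    shared_rank_window: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"tm": (8, 1.0), "non_tm": (0, 0.15)}
    )
    context_bias: dict[str, np.ndarray] = field(
        default_factory=lambda: {"tm": DEFAULT_TM_BIAS, "non_tm": DEFAULT_NONTM_BIAS}
    )
    redundancy: RedundancyPlan = field(default_factory=RedundancyPlan)
    n_organisms: int = 4
    strict_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 10:
            raise ValueError("length_range minimum must be >= 10")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with min <= max")
        for ctx, v in self.context_bias.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (20,) or np.any(v < 0) or v.sum() <= 0:
                raise ValueError(f"invalid context bias for {ctx!r}")
            self.context_bias[ctx] = v / v.sum()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "motif_laws" in raw:
            raw["motif_laws"] = {
                k: MotifLaw(**v) for k, v in raw["motif_laws"].items()
            }
        if "redundancy" in raw:
            raw["redundancy"] = RedundancyPlan(**raw["redundancy"])
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        if "context_bias" in raw:
            raw["context_bias"] = {
                k: _bias_vector(v) for k, v in raw["context_bias"].items()
            }
        return cls(**raw)


@dataclass(frozen=True)
class PlantedMotif:
    protein_ref: str
    start: int
    motif: str
    context: str  # "tm" | "non_tm"


@dataclass(frozen=True)
class PlantedCluster:
    members: tuple[str, ...]
    representative: str
    kind: str  # "duplicate" | "variant"


@dataclass
class GroundTruthManifest:
    motifs: list[PlantedMotif] = field(default_factory=list)
    clusters: list[PlantedCluster] = field(default_factory=list)
    cross_organism_copies: list[tuple[str, str]] = field(default_factory=list)

    def motif_set(self) -> set[tuple[str, int, str]]:
        return {(m.protein_ref, m.start, m.motif) for m in self.motifs}


# ---------------------------------------------------------------------------
# Motif-type sampling
# ---------------------------------------------------------------------------


class MotifSampler:
    """Draws 5-mer motif strings per context.

    Under a heavy-tailed law the motif type is drawn from a ranked,
    context-specific type list whose rank frequencies follow the law; under
    ``fixed_table`` the X residues are drawn independently from the
    context's weight vectors.  A configurable block of shared types is
    inserted into every context's list so TM/non-TM repertoires overlap.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.type_lists: dict[str, list[str]] = {}
        self.type_probs: dict[str, np.ndarray] = {}
        self._x_bias: dict[str, np.ndarray] = {}
        for ctx, bias in config.context_bias.items():
            self._x_bias[ctx] = self._effective_bias(bias)
        shared_bias = self._effective_bias(
            np.mean([config.context_bias[c] for c in config.context_bias], axis=0)
        )
        shared_types = self._draw_types(rng, shared_bias, config.n_shared_types, set())
        for ctx, law in config.motif_laws.items():
            if law.kind == "fixed_table":
                continue
            taken = set(shared_types)
            own = self._draw_types(
                rng,
                self._x_bias.get(ctx, shared_bias),
                max(law.n_types - len(shared_types), 0),
                taken,
            )
            types = own
            if shared_types:
                total = len(own) + len(shared_types)
                skip, top_frac = config.shared_rank_window.get(ctx, (0, 1.0))
                hi = max(int(round(top_frac * total)), skip + len(shared_types))
                hi = min(hi, total)
                slots = sorted(
                    skip
                    + rng.choice(hi - skip, size=len(shared_types), replace=False)
                )
                types = list(own)
                for slot, t in zip(slots, shared_types):
                    types.insert(min(slot, len(types)), t)
            law_n = MotifLaw(
                kind=law.kind, alpha=law.alpha, mu=law.mu, sigma=law.sigma,
                n_types=len(types),
            )
            self.type_lists[ctx] = types
            self.type_probs[ctx] = law_n.rank_weights()

    def _effective_bias(self, bias: np.ndarray) -> np.ndarray:
        v = np.asarray(bias, dtype=float).copy()
        if self.config.strict_background:
            v[_G_INDEX] = 0.0
        if v.sum() <= 0:
            raise ValueError("context bias degenerate after removing G")
        return v / v.sum()

    @staticmethod
    def _draw_types(
        rng: np.random.Generator,
        bias: np.ndarray,
        n: int,
        taken: set[str],
    ) -> list[str]:
        types: list[str] = []
        attempts = 0
        while len(types) < n and attempts < 200 * max(n, 1):
            xs = rng.choice(20, size=3, p=bias)
            motif = "G" + "".join(_AA[xs]) + "G"
            attempts += 1
            if motif not in taken:
                taken.add(motif)
                types.append(motif)
        while len(types) < n:  # fill from uniform if bias space exhausted
            xs = rng.integers(0, 20, size=3)
            motif = "G" + "".join(_AA[xs]) + "G"
            if motif not in taken:
                taken.add(motif)
                types.append(motif)
        return types

    def sample_motif_string(self, context: str, rng: np.random.Generator) -> str:
        law = self.config.motif_laws[context]
        if law.kind == "fixed_table":
            bias = self._x_bias[context]
            if bias.sum() <= 0:
                raise ValueError(f"empty weight vector for context {context!r}")
            xs = rng.choice(20, size=3, p=bias)
            return "G" + "".join(_AA[xs]) + "G"
        idx = rng.choice(len(self.type_lists[context]), p=self.type_probs[context])
        return self.type_lists[context][idx]


def sample_motif_string(
    config: SimConfig, context: str, rng: np.random.Generator
) -> str:
    """One-shot convenience wrapper around :class:`MotifSampler`."""
    return MotifSampler(config, rng).sample_motif_string(context, rng)


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------


def _place_tm_features(
    rng: np.random.Generator, length: int, mean_len: float
) -> list[TMFeature]:
    n_feat = 1 + int(rng.random() < 0.3)
    feats: list[TMFeature] = []
    for _ in range(n_feat):
        seg_len = int(np.clip(round(rng.normal(mean_len, 2.0)), 15, max(15, length // 2)))
        if seg_len >= length:
            continue
        for _attempt in range(50):
            start = int(rng.integers(1, length - seg_len + 2))
            end = start + seg_len - 1
            if all(end < f.start - 6 or start > f.end + 6 for f in feats):
                ev = Evidence.EXPERIMENTAL if rng.random() < 0.5 else Evidence.PREDICTED
                feats.append(TMFeature(start, end, ev))
                break
    return sorted(feats)


def _candidate_starts(
    length: int, features: Sequence[TMFeature], context: str
) -> list[int]:
    if context == "tm":
        out: list[int] = []
        for f in features:
            out.extend(range(f.start, f.end - 3))  # window fully inside
        return [s for s in out if s + 4 <= length]
    inside = np.zeros(length + 1, dtype=bool)
    for f in features:
        inside[f.start : f.end + 1] = True
    return [
        s
        for s in range(1, length - 3)
        if not inside[s : s + 5].any()
    ]


def generate_proteome(
    config: SimConfig,
) -> tuple[list[ProteinRecord], GroundTruthManifest]:
    """Build a proteome with planted motifs, TM features, and redundancy.

    Deterministic for a fixed seed.  If a protein cannot host the requested
    number of motifs, the count is reduced with a warning.
    """
    root = np.random.SeedSequence(config.seed)
    ss_types, ss_proteins, ss_redund = root.spawn(3)
    sampler = MotifSampler(config, np.random.default_rng(ss_types))
    rng = np.random.default_rng(ss_proteins)

    min_sep = 9 if config.strict_background else 5
    records: list[ProteinRecord] = []
    manifest = GroundTruthManifest()

    bg_bias = {
        ctx: sampler._effective_bias(bias)
        for ctx, bias in config.context_bias.items()
    }

    for i in range(config.n_proteins):
        pid = f"SYN{i:05d}"
        organism = f"Organism_{i % config.n_organisms}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        has_tm = rng.random() < config.tm_fraction
        features = _place_tm_features(rng, length, config.tm_segment_length) if has_tm else []

        # background, residue by residue, context-dependent
        seq = np.empty(length, dtype="<U1")
        inside = np.zeros(length + 1, dtype=bool)
        for f in features:
            inside[f.start : f.end + 1] = True
        n_in = int(inside[1:].sum())
        if n_in:
            seq[inside[1:]] = rng.choice(_AA, size=n_in, p=bg_bias["tm"])
        n_out = length - n_in
        if n_out:
            seq[~inside[1:]] = rng.choice(_AA, size=n_out, p=bg_bias["non_tm"])

        n_wanted = int(rng.poisson(config.motifs_per_protein))
        n_wanted = min(n_wanted, max(length // (min_sep + 5), 0))
        placed: list[tuple[int, str, str]] = []
        starts: list[int] = []
        candidates = {
            ctx: _candidate_starts(length, features, ctx) for ctx in ("tm", "non_tm")
        }
        attempts = 0
        has_shared_pool = "shared" in sampler.type_lists
        while len(placed) < n_wanted and attempts < 60 * max(n_wanted, 1):
            attempts += 1
            from_shared = (
                has_shared_pool and rng.random() < config.shared_motif_fraction
            )
            if from_shared:
                context = (
                    "tm"
                    if (features and rng.random() < config.shared_tm_prob)
                    else "non_tm"
                )
            else:
                context = (
                    "tm"
                    if (features and rng.random() < config.tm_motif_fraction)
                    else "non_tm"
                )
            pool = candidates[context]
            if not pool:
                context = "non_tm" if context == "tm" else "tm"
                pool = candidates[context]
                if not pool:
                    break
            s = int(pool[rng.integers(len(pool))])
            if any(abs(s - s0) < min_sep for s0 in starts):
                continue
            motif = sampler.sample_motif_string(
                "shared" if from_shared else context, rng
            )
            starts.append(s)
            placed.append((s, motif, context))
        if len(placed) < n_wanted:
            logger.warning(
                "%s: placed %d of %d requested motifs", pid, len(placed), n_wanted
            )
        for s, motif, context in placed:
            seq[s - 1 : s + 4] = list(motif)
            manifest.motifs.append(
                PlantedMotif(protein_ref=pid, start=s, motif=motif, context=context)
            )
        records.append(
            ProteinRecord(
                uniprot_id=pid,
                sequence="".join(seq),
                organism=organism,
                taxonomy=("Synthetica", organism),
                tm_features=features,
            )
        )

    _inject_redundancy(config, records, manifest, np.random.default_rng(ss_redund))
    return records, manifest


def _protein_motifs(
    manifest: GroundTruthManifest, pid: str
) -> list[PlantedMotif]:
    return [m for m in manifest.motifs if m.protein_ref == pid]


def _copy_with_motifs(
    manifest: GroundTruthManifest, src: ProteinRecord, new_id: str, organism: str
) -> ProteinRecord:
    for m in _protein_motifs(manifest, src.uniprot_id):
        manifest.motifs.append(
            PlantedMotif(
                protein_ref=new_id, start=m.start, motif=m.motif, context=m.context
            )
        )
    return ProteinRecord(
        uniprot_id=new_id,
        sequence=src.sequence,
        organism=organism,
        taxonomy=src.taxonomy,
        tm_features=list(src.tm_features),
    )


def _inject_redundancy(
    config: SimConfig,
    records: list[ProteinRecord],
    manifest: GroundTruthManifest,
    rng: np.random.Generator,
) -> None:
    plan = config.redundancy
    n_base = len(records)
    needed = plan.n_duplicate_pairs + plan.n_variant_clusters + plan.n_cross_organism_duplicates
    if needed == 0 or n_base == 0:
        return
    if needed > n_base:
        raise ValueError("redundancy plan requires more base proteins than generated")
    chosen = rng.choice(n_base, size=needed, replace=False)
    k = 0

    for d in range(plan.n_duplicate_pairs):
        base = records[chosen[k]]
        k += 1
        dup_id = f"DUP{d:03d}"
        records.append(_copy_with_motifs(manifest, base, dup_id, base.organism))
        members = tuple(sorted((base.uniprot_id, dup_id)))
        manifest.clusters.append(
            PlantedCluster(members=members, representative=min(members), kind="duplicate")
        )

    for c in range(plan.n_variant_clusters):
        base = records[chosen[k]]
        k += 1
        member_ids = [base.uniprot_id]
        protected = np.zeros(len(base.sequence) + 1, dtype=bool)
        for m in _protein_motifs(manifest, base.uniprot_id):
            protected[m.start : m.start + 5] = True
        free = [
            p
            for p in range(1, len(base.sequence) + 1)
            if not protected[p] and base.sequence[p - 1] != "G"
        ]
        L = len(base.sequence)
        n_sub = max(1, int(L * (100.0 - plan.variant_identity) / 100.0 * 0.8))
        n_sub = min(n_sub, len(free))
        for v in range(plan.variant_cluster_size - 1):
            var_id = f"VAR{c:02d}{v:02d}"
            seq = list(base.sequence)
            pos = rng.choice(len(free), size=n_sub, replace=False)
            for p in pos:
                old = seq[free[p] - 1]
                choices = [a for a in STANDARD_RESIDUES if a not in (old, "G")]
                seq[free[p] - 1] = choices[int(rng.integers(len(choices)))]
            var_seq = "".join(seq)
            ident = pairwise_identity(base.sequence, var_seq)
            assert ident >= plan.variant_identity, (
                f"variant identity {ident:.2f} below plan {plan.variant_identity}"
            )
            var = ProteinRecord(
                uniprot_id=var_id,
                sequence=var_seq,
                organism=base.organism,
                taxonomy=base.taxonomy,
                tm_features=list(base.tm_features),
            )
            for m in _protein_motifs(manifest, base.uniprot_id):
                manifest.motifs.append(
                    PlantedMotif(
                        protein_ref=var_id, start=m.start, motif=m.motif,
                        context=m.context,
                    )
                )
            records.append(var)
            member_ids.append(var_id)
        members = tuple(sorted(member_ids))
        manifest.clusters.append(
            PlantedCluster(members=members, representative=min(members), kind="variant")
        )

    for x in range(plan.n_cross_organism_duplicates):
        base = records[chosen[k]]
        k += 1
        other = f"Organism_X{x}"
        new_id = f"XDU{x:03d}"
        records.append(_copy_with_motifs(manifest, base, new_id, other))
        manifest.cross_organism_copies.append((base.uniprot_id, new_id))


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------


def write_proteome(
    records: Sequence[ProteinRecord],
    manifest: GroundTruthManifest,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + TM-feature TSV + metadata TSV + manifest TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "tm_features": outdir / "tm_features.tsv",
        "metadata": outdir / "proteins.tsv",
        "manifest_motifs": outdir / "manifest_motifs.tsv",
        "manifest_clusters": outdir / "manifest_clusters.tsv",
    }
    write_fasta(records, paths["fasta"])
    write_tm_features({r.uniprot_id: r.tm_features for r in records}, paths["tm_features"])
    write_protein_metadata(records, paths["metadata"])
    pd.DataFrame(
        [(m.protein_ref, m.start, m.motif, m.context) for m in manifest.motifs],
        columns=["protein_ref", "start", "motif", "context"],
    ).to_csv(paths["manifest_motifs"], sep="\t", index=False)
    pd.DataFrame(
        [(";".join(c.members), c.representative, c.kind) for c in manifest.clusters],
        columns=["members", "representative", "kind"],
    ).to_csv(paths["manifest_clusters"], sep="\t", index=False)
    return paths


def read_manifest(outdir: str | Path) -> GroundTruthManifest:
    outdir = Path(outdir)
    motifs_df = pd.read_csv(outdir / "manifest_motifs.tsv", sep="\t", dtype={"protein_ref": str, "motif": str})
    clusters_df = pd.read_csv(outdir / "manifest_clusters.tsv", sep="\t", dtype=str)
    manifest = GroundTruthManifest()
    for row in motifs_df.itertuples(index=False):
        manifest.motifs.append(
            PlantedMotif(str(row.protein_ref), int(row.start), str(row.motif), str(row.context))
        )
    for row in clusters_df.itertuples(index=False):
        manifest.clusters.append(
            PlantedCluster(tuple(str(row.members).split(";")), str(row.representative), str(row.kind))
        )
    return manifest
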