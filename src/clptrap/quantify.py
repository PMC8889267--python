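"""Spectral-count quantification of affinity-enrichment proteomics runs.

Peptide-spectrum-match (PSM) counts are turned into per-protein quantities:

* ``SPC`` — total spectral counts: every spectrum of every peptide matching
  the protein, shared or not.
* ``uSPC`` — unique spectral counts: spectra of peptides whose accession set
  is exactly this protein.
* ``adjSPC`` — adjusted spectral counts: uSPC plus each shared peptide's
  spectra apportioned among its accessions in proportion to their unique
  spectral counts in that sample.
* ``NadjSPC`` — adjSPC normalised per sample, either to the sample total or
  to a declared bait protein set.

The module also implements the two dataset-level cleanups used with this
kind of data: discarding proteins identified only through peptides shared
with better-supported proteins, and grouping proteins that share most of
their matched peptides into families quantified as one unit.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Iterable, Mapping, Sequence
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "SampleKey",
    "PeptideMatch",
    "PSMTable",
    "QuantMatrix",
    "Grouping",
    "load_psm_table",
    "apportion_shared",
    "discard_fully_shared",
    "group_families",
    "aggregate_groups",
    "normalize",
    "write_quant_long",
]

GENOTYPES = ("TRAP", "WT", "CONTROL")


class SampleKey(NamedTuple):
    """One MS run: genotype x biological replicate x technical replicate."""

    genotype: str
    bioreplicate: int
    techreplicate: int

    @property
    def label(self) -> str:
        return f"{self.genotype}_b{self.bioreplicate}_t{self.techreplicate}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        try:
            genotype, b, t = label.split("_")
            if not (b.startswith("b") and t.startswith("t")):
                raise ValueError
            key = cls(genotype, int(b[1:]), int(t[1:]))
        except ValueError as exc:
            raise ValueError(f"malformed sample label {label!r}; expected "
                             "'GENOTYPE_bN_tN'") from exc
        key.validate()
        return key

    def validate(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.bioreplicate < 1 or self.techreplicate < 1:
            raise ValueError("replicate indices must be positive")


class PeptideMatch(NamedTuple):
    """A peptide sequence, the accessions it matches, and per-sample counts."""

    peptide: str
    accessions: frozenset
    counts: Mapping[SampleKey, int]


def make_roster(genotypes: Sequence[str] = ("TRAP", "WT"),
                n_bioreps: int = 3, n_techreps: int = 3) -> tuple:
    """Full-factorial sample roster in a fixed deterministic order."""
    roster = tuple(
        SampleKey(g, b, t)
        for g in genotypes
        for b in range(1, n_bioreps + 1)
        for t in range(1, n_techreps + 1)
    )
    for key in roster:
        key.validate()
    return roster


@dataclasses.dataclass(frozen=True)
class PSMTable:
    """Validated peptide-level count table.

    ``counts`` is an integer array of shape (n_peptides, n_samples) aligned
    with ``peptides`` and ``roster``; ``accession_sets`` holds one frozenset
    of protein accessions per peptide.
    """

    peptides: tuple
    accession_sets: tuple
    counts: np.ndarray
    roster: tuple

    def __post_init__(self):
        if len(self.peptides) != len(set(self.peptides)):
            raise ValueError("duplicate peptides must be pre-aggregated")
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("duplicate sample keys in roster")
        if self.counts.shape != (len(self.peptides), len(self.roster)):
            raise ValueError("counts shape does not match peptides x roster")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum counts")
        for pep, accs in zip(self.peptides, self.accession_sets):
            if not accs:
                raise ValueError(f"peptide {pep!r} has an empty accession set")

    @classmethod
    def from_matches(cls, matches: Iterable[PeptideMatch],
                     roster: Sequence[SampleKey]) -> "PSMTable":
        roster = tuple(roster)
        pos = {k: i for i, k in enumerate(roster)}
        agg: dict = {}
        accs: dict = {}
        for m in matches:
            row = agg.setdefault(m.peptide, np.zeros(len(roster), dtype=np.int64))
            if m.peptide in accs and accs[m.peptide] != frozenset(m.accessions):
                raise ValueError(
                    f"peptide {m.peptide!r} listed with conflicting accession sets")
            accs[m.peptide] = frozenset(m.accessions)
            for key, n in m.counts.items():
                if key not in pos:
                    raise ValueError(f"sample {key!r} not in roster")
                row[pos[key]] += int(n)
        peptides = tuple(agg)
        counts = (np.vstack([agg[p] for p in peptides])
                  if peptides else np.zeros((0, len(roster)), dtype=np.int64))
        return cls(peptides, tuple(accs[p] for p in peptides), counts, roster)

    @property
    def accessions(self) -> tuple:
        out: set = set()
        for s in self.accession_sets:
            out |= s
        return tuple(sorted(out))

    @property
    def sample_labels(self) -> list:
        return [k.label for k in self.roster]

    def total_spectra(self) -> np.ndarray:
        """Per-sample total spectrum counts over all peptides."""
        return self.counts.sum(axis=0)


@dataclasses.dataclass
class QuantMatrix:
    """Per-protein per-sample quantities plus grouping/discard metadata.

    All frames are indexed by accession with one column per sample label;
    ``uSPC <= adjSPC <= SPC`` holds entrywise.
    """

    spc: pd.DataFrame
    uspc: pd.DataFrame
    adjspc: pd.DataFrame
    n_peptides: pd.Series
    roster: tuple
    nadjspc: pd.DataFrame | None = None
    discarded: pd.Series | None = None
    group_id: pd.Series | None = None
    normalization: str = "none"

    def __post_init__(self):
        if self.discarded is None:
            self.discarded = pd.Series(False, index=self.spc.index)

    @property
    def accessions(self) -> pd.Index:
        return self.spc.index

    def retained(self) -> pd.Index:
        return self.spc.index[~self.discarded]

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            spc=self.spc.copy(), uspc=self.uspc.copy(),
            adjspc=self.adjspc.copy(), n_peptides=self.n_peptides.copy(),
            roster=self.roster,
            nadjspc=None if self.nadjspc is None else self.nadjspc.copy(),
            discarded=self.discarded.copy(),
            group_id=None if self.group_id is None else self.group_id.copy(),
            normalization=self.normalization)


def load_psm_table(path, roster: Sequence[SampleKey],
                   accession_sep: str = ";") -> PSMTable:
    """Read a TSV of peptide, accessions, and one count column per sample.

    Sample columns must be labelled ``GENOTYPE_bN_tN`` and every column must
    appear in ``roster``. Duplicate peptide rows are aggregated by summation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "peptide" not in df.columns or "accessions" not in df.columns:
        raise ValueError("PSM table must have 'peptide' and 'accessions' columns")
    roster = tuple(roster)
    known = {k.label for k in roster}
    sample_cols = [c for c in df.columns if c not in ("peptide", "accessions")]
    for col in sample_cols:
        if col not in known:
            raise ValueError(f"sample column {col!r} is not in the roster")
    matches = []
    label_key = {k.label: k for k in roster}
    for i, row in df.iterrows():
        accs = frozenset(a.strip() for a in str(row["accessions"]).split(accession_sep)
                         if a.strip())
        if not accs or pd.isna(row["accessions"]):
            raise ValueError(f"empty accession field at data row {i + 1}")
        counts = {label_key[c]: int(row[c]) for c in sample_cols}
        matches.append(PeptideMatch(row["peptide"], accs, counts))
    return PSMTable.from_matches(matches, roster)


def _index_proteins(psm: PSMTable):
    accessions = list(psm.accessions)
    aidx = {a: i for i, a in enumerate(accessions)}
    acc_idx_sets = [np.fromiter((aidx[a] for a in sorted(s)), dtype=np.intp)
                    for s in psm.accession_sets]
    return accessions, acc_idx_sets


def apportion_shared(psm: PSMTable) -> QuantMatrix:
    """Compute SPC/uSPC/adjSPC, splitting shared peptides by unique counts.

    Within each sample, a shared peptide's spectra are divided among its
    accessions in proportion to each accession's uSPC in that sample; when
    all accessions have zero uSPC the spectra are split equally.
    """
    accessions, acc_idx_sets = _index_proteins(psm)
    n_prot, n_samp = len(accessions), len(psm.roster)
    counts = psm.counts.astype(float)

    spc = np.zeros((n_prot, n_samp))
    uspc = np.zeros((n_prot, n_samp))
    for p, idxs in enumerate(acc_idx_sets):
        spc[idxs] += counts[p]
        if len(idxs) == 1:
            uspc[idxs[0]] += counts[p]

    adjspc = uspc.copy()
    for p, idxs in enumerate(acc_idx_sets):
        if len(idxs) == 1 or not counts[p].any():
            continue
        w = uspc[idxs, :]                       # (k, n_samp)
        tot = w.sum(axis=0)
        share = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 1.0 / len(idxs))
        adjspc[idxs, :] += counts[p] * share

    labels = psm.sample_labels
    npep = np.zeros(n_prot, dtype=np.int64)
    for idxs in acc_idx_sets:
        npep[idxs] += 1
    return QuantMatrix(
        spc=pd.DataFrame(spc, index=accessions, columns=labels),
        uspc=pd.DataFrame(uspc, index=accessions, columns=labels),
        adjspc=pd.DataFrame(adjspc, index=accessions, columns=labels),
        n_peptides=pd.Series(npep, index=accessions, name="n_peptides"),
        roster=psm.roster)


def discard_fully_shared(psm: PSMTable, qm: QuantMatrix) -> QuantMatrix:
    """Drop proteins supported only by peptides shared with unique-peptide proteins.

    A protein is discarded when its total uSPC over all samples is zero and
    every one of its matched peptides is shared with at least one protein
    whose total uSPC is nonzero. Shared spectra are then re-apportioned over
    the reduced accession sets, so discarded proteins end with zero adjSPC.
    """
    total_uspc = qm.uspc.sum(axis=1)
    nonzero = set(total_uspc.index[total_uspc > 0])
    pep_of: dict = {}
    for accs in psm.accession_sets:
        for a in accs:
            pep_of.setdefault(a, []).append(accs)
    discarded = set()
    for acc in qm.accessions:
        if total_uspc[acc] > 0:
            continue
        peps = pep_of.get(acc, [])
        if peps and all(any(o != acc and o in nonzero for o in accs)
                        for accs in peps):
            discarded.add(acc)
    if not discarded:
        out = qm.copy()
        out.discarded = pd.Series(False, index=qm.accessions)
        return out

    reduced = []
    for pep, accs, row in zip(psm.peptides, psm.accession_sets, psm.counts):
        keep = accs - discarded
        if not keep:
            continue  # cannot happen under the rule; defensive
        reduced.append(PeptideMatch(pep, keep,
                                    dict(zip(psm.roster, row.tolist()))))
    out = apportion_shared(PSMTable.from_matches(reduced, psm.roster))
    # reinstate discarded proteins as zero rows, flagged
    full_index = qm.accessions
    for frame_name in ("spc", "uspc", "adjspc"):
        frame = getattr(out, frame_name).reindex(full_index, fill_value=0.0)
        setattr(out, frame_name, frame)
    out.n_peptides = qm.n_peptides.copy()
    out.discarded = pd.Series([a in discarded for a in full_index],
                              index=full_index)
    return out


@dataclasses.dataclass(frozen=True)
class Grouping:
    """Protein families from peptide sharing: label -> member accessions."""

    members: Mapping[str, tuple]
    label_of: Mapping[str, str]


def group_families(psm: PSMTable, threshold: float = 0.80) -> Grouping:
    """Group proteins sharing more than ``threshold`` of their matched peptides.

    Proteins i and j are linked when the shared peptide fraction of either
    protein's own peptide set strictly exceeds the threshold; connected
    components become families, labelled by the member with the highest
    total uSPC (ties broken by accession order).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    pepset: dict = {}
    for pep, accs in zip(psm.peptides, psm.accession_sets):
        for a in accs:
            pepset.setdefault(a, set()).add(pep)
    accessions = sorted(pepset)
    parent = {a: a for a in accessions}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    # proteins share a peptide iff they co-occur in its accession set, so
    # candidate pairs can be enumerated per peptide
    pairs = set()
    for accs in psm.accession_sets:
        accs = sorted(accs)
        for i in range(len(accs)):
            for j in range(i + 1, len(accs)):
                pairs.add((accs[i], accs[j]))
    for a, b in pairs:
        inter = len(pepset[a] & pepset[b])
        if inter / len(pepset[a]) > threshold or inter / len(pepset[b]) > threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    qm = apportion_shared(psm)
    total_uspc = qm.uspc.sum(axis=1)
    comps: dict = {}
    for a in accessions:
        comps.setdefault(find(a), []).append(a)
    members, label_of = {}, {}
    for comp in comps.values():
        label = max(comp, key=lambda a: (total_uspc.get(a, 0.0), a))
        members[label] = tuple(sorted(comp))
        for a in comp:
            label_of[a] = label
    return Grouping(members=members, label_of=label_of)


def aggregate_groups(qm: QuantMatrix, grouping: Grouping) -> QuantMatrix:
    """Sum member quantities into one row per family, keyed by its label."""
    key = pd.Series({a: grouping.label_of.get(a, a) for a in qm.accessions})

    def agg(frame):
        return frame.groupby(key).sum().sort_index()

    out = QuantMatrix(
        spc=agg(qm.spc), uspc=agg(qm.uspc), adjspc=agg(qm.adjspc),
        n_peptides=qm.n_peptides.groupby(key).sum().sort_index(),
        roster=qm.roster,
        discarded=qm.discarded.groupby(key).all().sort_index(),
        normalization=qm.normalization)
    out.group_id = pd.Series(out.spc.index, index=out.spc.index, name="group_id")
    return out


def normalize(qm: QuantMatrix, mode: str = "total",
              bait_accessions: Sequence[str] | None = None) -> QuantMatrix:
    """Attach NadjSPC: adjSPC over the per-sample total or bait total."""
    if mode not in ("total", "bait"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = qm.copy()
    adj = out.adjspc.loc[out.retained()]
    if mode == "total":
        denom = adj.sum(axis=0)
    else:
        if not bait_accessions:
            raise ValueError("mode='bait' requires a non-empty bait set")
        baits = [b for b in bait_accessions if b in adj.index]
        if not baits:
            raise ValueError("no bait accession present in the data")
        denom = adj.loc[baits].sum(axis=0)
        zero = denom.index[denom == 0]
        if len(zero):
            raise ValueError(f"bait adjSPC total is zero in sample {zero[0]!r}")
    nadj = out.adjspc.div(denom.replace(0, np.nan), axis=1).fillna(0.0)
    nadj.loc[out.discarded[out.discarded].index] = 0.0
    out.nadjspc = nadj
    out.normalization = mode
    return out


def write_quant_long(qm: QuantMatrix, path) -> None:
    """Write a long-format TSV: accession, sample, SPC, uSPC, adjSPC, NadjSPC."""
    frames = {"SPC": qm.spc, "uSPC": qm.uspc, "adjSPC": qm.adjspc}
    if qm.nadjspc is not None:
        frames["NadjSPC"] = qm.nadjspc
    long = pd.concat(
        {name: f.stack() for name, f in frames.items()}, axis=1)
    long.index.names = ["accession", "sample"]
    long = long.reset_index()
    long["discarded"] = long["accession"].map(qm.discarded)
    buf = io.StringIO()
    long.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
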