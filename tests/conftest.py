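import numpy as np
import pytest

from clptrap.quantify import PSMTable, PeptideMatch, make_roster


@pytest.fixture
def roster2x1():
    """Two genotypes, one bioreplicate, one technical run."""
    return make_roster(("TRAP", "WT"), 1, 1)


@pytest.fixture
def roster_full():
    """The study design: TRAP/WT x 3 bioreps x 3 tech runs."""
    return make_roster(("TRAP", "WT"), 3, 3)


def psm_from_rows(rows, roster):
    """rows: (peptide, accession-set, per-sample counts in roster order)."""
    matches = [
        PeptideMatch(pep, frozenset(accs), dict(zip(roster, counts)))
        for pep, accs, counts in rows
    ]
    return PSMTable.from_matches(matches, roster)


def random_psm(rng, roster, n_proteins=30, n_peptides=200, shared_frac=0.2,
               max_count=12):
    """Random PSM instance for oracle comparisons."""
    proteins = [f"P{i}" for i in range(n_proteins)]
    rows = []
    for p in range(n_peptides):
        k = 1 if rng.random() >= shared_frac else int(rng.integers(2, 4))
        accs = rng.choice(proteins, size=min(k, n_proteins), replace=False)
        counts = rng.integers(0, max_count, size=len(roster))
        rows.append((f"PEP{p}", set(accs.tolist()), counts.tolist()))
    return psm_from_rows(rows, roster)


def apportion_oracle(psm):
    """Independent per-peptide apportionment: plain dict/loop arithmetic."""
    samples = list(range(len(psm.roster)))
    accs = sorted({a for s in psm.accession_sets for a in s})
    uspc = {a: [0.0] * len(samples) for a in accs}
    for accset, row in zip(psm.accession_sets, psm.counts):
        if len(accset) == 1:
            (a,) = accset
            for s in samples:
                uspc[a][s] += row[s]
    adj = {a: list(u) for a, u in uspc.items()}
    for accset, row in zip(psm.accession_sets, psm.counts):
        if len(accset) == 1:
            continue
        members = sorted(accset)
        for s in samples:
            total_u = sum(uspc[a][s] for a in members)
            for a in members:
                if total_u > 0:
                    share = uspc[a][s] / total_u
                else:
                    share = 1.0 / len(members)
                adj[a][s] += row[s] * share
    return uspc, adj


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
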