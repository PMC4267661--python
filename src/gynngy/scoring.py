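"""Donor splice-site strength on the 9-mer convention.

A donor is scored on its 9-mer: the last 3 exonic and first 6 intronic
bases in transcript orientation.  Two probabilistic consensus models are
provided, both trained on a set of (typically constitutive) donor
9-mers and scored as log2 odds against a background model:

WMM  position weight matrix; independent per-position base frequencies.
MM1  first-order Markov chain; an initial-base distribution plus one
     transition matrix per adjacent position pair.

Scores are additive over positions (WMM) / transitions (MM1), finite
for every 9-mer thanks to an additive pseudocount.  For a tandem site
the absolute score difference |SS_distal - SS_proximal| measures how
closely the two donors resemble each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gynngy.util import tx_fetch

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
NINE = 9


def extract_9mer(genome, chrom: str, strand: str, donor: int) -> str:
    """The 3-exonic + 6-intronic 9-mer of a donor (first intronic base).

    Reverse-complemented for minus-strand donors.  Raises on donors too
    close to a contig end to supply all 9 bases.
    """
    chrom_len = len(genome[chrom])
    if strand == "+":
        lo, hi = donor - 3, donor + 6
    else:
        lo, hi = donor - 5, donor + 4
    if lo < 0 or hi > chrom_len:
        raise ValueError(
            f"donor {chrom}:{strand}:{donor} too close to contig end for a 9-mer"
        )
    return tx_fetch(genome, chrom, strand, lo, hi)


def _validate_9mers(seqs: list[str]) -> list[str]:
    seqs = [s.upper() for s in seqs]
    for s in seqs:
        if len(s) != NINE or any(b not in _IDX for b in s):
            raise ValueError(f"not an ACGT 9-mer: {s!r}")
    return seqs


@dataclass
class DonorModel:
    """Trained donor consensus model (log2-odds parameterisation)."""

    kind: str  # 'WMM' or 'MM1'
    n_training: int
    pseudocount: float
    background: np.ndarray  # per-base background probabilities
    wmm: np.ndarray | None = None  # 9 x 4 log-odds
    initial: np.ndarray | None = None  # 4, log-odds at position 1
    transitions: np.ndarray | None = None  # 8 x 4 x 4 log-odds

    def score(self, ninemer: str) -> float:
        (s,) = _validate_9mers([ninemer])
        idx = [_IDX[b] for b in s]
        if self.kind == "WMM":
            return float(sum(self.wmm[i, idx[i]] for i in range(NINE)))
        total = self.initial[idx[0]]
        for i in range(NINE - 1):
            total += self.transitions[i, idx[i], idx[i + 1]]
        return float(total)


def train_donor_model(
    training: list[str],
    kind: str = "WMM",
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> DonorModel:
    """Train a WMM or first-order Markov donor model on 9-mers.

    Frequencies get an additive pseudocount so every 9-mer scores
    finitely; the background defaults to uniform 0.25 per base and, for
    MM1, to a uniform transition chain.
    """
    seqs = _validate_9mers(list(training))
    if not seqs:
        raise ValueError("empty training set")
    if kind not in ("WMM", "MM1"):
        raise ValueError(f"unknown model kind {kind!r}")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 probabilities summing to 1")
    mat = np.zeros((NINE, 4))
    for s in seqs:
        for i, b in enumerate(s):
            mat[i, _IDX[b]] += 1
    freq = (mat + pseudocount) / (mat + pseudocount).sum(axis=1, keepdims=True)
    if kind == "WMM":
        return DonorModel(
            kind="WMM",
            n_training=len(seqs),
            pseudocount=pseudocount,
            background=bg,
            wmm=np.log2(freq / bg),
        )
    trans_counts = np.zeros((NINE - 1, 4, 4))
    for s in seqs:
        for i in range(NINE - 1):
            trans_counts[i, _IDX[s[i]], _IDX[s[i + 1]]] += 1
    tfreq = (trans_counts + pseudocount) / (trans_counts + pseudocount).sum(
        axis=2, keepdims=True
    )
    return DonorModel(
        kind="MM1",
        n_training=len(seqs),
        pseudocount=pseudocount,
        background=bg,
        initial=np.log2(freq[0] / bg),
        transitions=np.log2(tfreq / bg[None, None, :]),
    )


@dataclass
class ScorePair:
    site_id: str
    ss_distal: float
    ss_proximal: float

    @property
    def abs_diff(self) -> float:
        return abs(self.ss_distal - self.ss_proximal)


def score_pair(
    genome, chrom: str, strand: str, distal_donor: int, model: DonorModel,
    site_id: str | None = None,
) -> ScorePair:
    """Score both donors of a tandem site with the same model."""
    from gynngy.catalog import _tx_offset

    proximal = _tx_offset(strand, distal_donor, 4)
    return ScorePair(
        site_id=site_id or f"{chrom}:{strand}:{distal_donor}",
        ss_distal=model.score(extract_9mer(genome, chrom, strand, distal_donor)),
        ss_proximal=model.score(extract_9mer(genome, chrom, strand, proximal)),
    )


def consensus_matrix(ninemers: list[str]) -> pd.DataFrame:
    """Per-position base frequencies of a group of 9-mers.

    Rows are positions 1..9 (3 exonic + 6 intronic), columns A/C/G/T;
    each row sums to 1 — the column-profile convention of sequence-logo
    rendering.  Empty groups are an error.
    """
    seqs = _validate_9mers(list(ninemers))
    if not seqs:
        raise ValueError("empty group")
    mat = np.zeros((NINE, 4))
    for s in seqs:
        for i, b in enumerate(s):
            mat[i, _IDX[b]] += 1
    freq = mat / mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, index=range(1, NINE + 1), columns=list(BASES))


def split_by_major_donor(
    catalog: pd.DataFrame, counts: pd.DataFrame
) -> dict[str, list[str]]:
    """Site ids split into distal-major / proximal-major by mean usage."""
    out = {"distal_major": [], "proximal_major": []}
    totals = counts.groupby("site_id")[["distal_reads", "proximal_reads"]].sum()
    for site_id, row in totals.iterrows():
        key = (
            "distal_major"
            if row["distal_reads"] >= row["proximal_reads"]
            else "proximal_major"
        )
        out[key].append(site_id)
    return out
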