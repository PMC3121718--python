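"""Promoter transcriptional-regulatory-element (TRE) analysis.

Scans upstream sequences for transcription-factor binding motifs given as
IUPAC consensus strings or position-weight matrices, builds the binary
gene x motif interaction matrix with a >5% prevalence filter, and tests
per-motif overrepresentation in a candidate gene list against a reference
set.  The flagship example is the HNF-4 homodimer site, consensus
AGGTCAaAGGTCA (case is ignored; the lowercase a is an A).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from scipy import stats

__all__ = [
    "Motif",
    "scan_promoter",
    "build_interaction_matrix",
    "tre_enrichment",
    "read_motifs",
    "PromoterMotifAnalysis",
    "TREInteractionMatrix",
    "HNF4_CONSENSUS",
]

HNF4_CONSENSUS = "AGGTCAAAGGTCA"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Motif:
    """A binding-site motif: IUPAC consensus or PWM with a score threshold.

    PWM columns are positions; rows are A, C, G, T probabilities summing
    to 1.  ``threshold`` is the minimum log2-odds score (against the
    background) for a window to count as a hit.  ``strand`` is "both" or
    "forward".
    """

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None
    threshold: float = 0.0
    strand: str = "both"
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("motif needs exactly one of consensus or pwm")
        if self.strand not in ("both", "forward"):
            raise ValueError("strand must be 'both' or 'forward'")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(_IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")
            self.consensus = self.consensus.upper()
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must have 4 rows (A, C, G, T)")
            if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
                raise ValueError("PWM columns must sum to 1")
            if not np.isfinite(self.threshold):
                raise ValueError("PWM threshold must be finite")

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


def _iupac_regex(consensus: str) -> re.Pattern:
    # overlapping matches via lookahead; sequence N only matches motif N
    return re.compile("(?=" + "".join(f"[{_IUPAC[c]}]" for c in consensus) + ")")


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _pwm_positions(seq: str, pwm: np.ndarray, threshold: float,
                   background: np.ndarray) -> list:
    L = pwm.shape[1]
    n = len(seq)
    if n < L:
        return []
    with np.errstate(divide="ignore"):
        logodds = np.log2(np.maximum(pwm, 1e-12) / background[:, None])
    enc = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)          # windows containing N never hit
    scores = np.full(n - L + 1, -np.inf)
    if valid.any():
        w = windows[valid]
        scores[valid] = logodds[w, np.arange(L)[None, :]].sum(axis=1)
    return list(np.flatnonzero(scores >= threshold))


def scan_promoter(seq: str, motif: Motif) -> tuple[int, list]:
    """Count motif occurrences in one promoter sequence.

    Returns ``(count, positions)`` with 0-based, half-open window starts on
    the forward coordinate system.  In "both" mode the reverse strand is
    scanned as well (by matching the reverse-complemented motif on the
    forward sequence).  Overlapping matches are all counted; an N in the
    sequence never satisfies a non-N motif position.
    """
    seq = _validate_seq(seq)
    if not seq:
        return 0, []
    positions = []
    if motif.consensus is not None:
        positions += [m.start() for m in _iupac_regex(motif.consensus).finditer(seq)]
        if motif.strand == "both":
            rc = reverse_complement(motif.consensus)
            rc_pat = _iupac_regex(rc)
            positions += [m.start() for m in rc_pat.finditer(seq)]
    else:
        positions += _pwm_positions(seq, motif.pwm, motif.threshold, motif.background)
        if motif.strand == "both":
            rc_pwm = motif.pwm[::-1, ::-1]      # complement rows, reverse columns
            positions += _pwm_positions(seq, rc_pwm, motif.threshold,
                                        motif.background[::-1])
    positions = sorted(positions)
    return len(positions), positions


@dataclass
class TREInteractionMatrix:
    """Binary gene x motif promoter-hit matrix after the prevalence filter."""

    hits: pd.DataFrame                 # genes x retained motifs, entries 0/1
    prevalence: pd.Series              # all scanned motifs
    dropped: list
    skipped_genes: list
    promoter_length: int


def build_interaction_matrix(promoters: dict, motifs, genes=None,
                             prevalence_min: float = 0.05) -> TREInteractionMatrix:
    """Scan every promoter for every motif and apply the prevalence filter.

    ``promoters`` maps gene id -> sequence.  Motifs found in a fraction of
    promoters at or below ``prevalence_min`` are dropped (and logged);
    genes without a promoter are skipped with a warning.
    """
    genes = list(genes) if genes is not None else sorted(promoters)
    skipped = [g for g in genes if g not in promoters]
    if skipped:
        warnings.warn(f"{len(skipped)} genes lack promoters and were skipped")
    genes = [g for g in genes if g in promoters]
    if not genes:
        raise ValueError("no genes with promoter sequences")
    data = {}
    for motif in motifs:
        col = [1 if scan_promoter(promoters[g], motif)[0] > 0 else 0 for g in genes]
        data[motif.name] = col
    full = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    prevalence = full.mean(axis=0)
    keep = prevalence[prevalence > prevalence_min].index.tolist()
    dropped = [m for m in full.columns if m not in keep]
    lengths = {len(s) for s in promoters.values()}
    plen = lengths.pop() if len(lengths) == 1 else -1
    return TREInteractionMatrix(hits=full[keep], prevalence=prevalence,
                                dropped=dropped, skipped_genes=skipped,
                                promoter_length=plen)


def tre_enrichment(matrix: TREInteractionMatrix | pd.DataFrame, candidate_genes,
                   reference_genes, alpha: float = 0.05) -> pd.DataFrame:
    """Per-motif overrepresentation of promoter hits in the candidates.

    When the candidates are a subset of the reference the null is
    hypergeometric sampling of the candidate list from the reference;
    when the two sets are disjoint a one-sided Fisher exact test on the
    2x2 hit table is used.  Motifs ordered by ascending p.
    """
    hits = matrix.hits if isinstance(matrix, TREInteractionMatrix) else matrix
    cand = [g for g in candidate_genes if g in hits.index]
    ref = [g for g in reference_genes if g in hits.index]
    cset, rset = set(cand), set(ref)
    if not (cset <= rset or not (cset & rset)):
        raise ValueError("candidates must be a subset of, or disjoint from, the reference")
    subset_mode = cset <= rset
    rows = []
    for motif in hits.columns:
        k = int(hits.loc[cand, motif].sum())
        K = int(hits.loc[ref, motif].sum())
        if k == 0 and K == 0:
            p = 1.0
        elif subset_mode:
            p = float(stats.hypergeom.sf(k - 1, len(ref), K, len(cand)))
        else:
            table = [[k, len(cand) - k], [K, len(ref) - K]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append({"motif": motif, "candidate_hits": k, "candidate_n": len(cand),
                     "reference_hits": K, "reference_n": len(ref),
                     "p_value": min(p, 1.0), "significant": p < alpha})
    return (pd.DataFrame(rows)
            .sort_values(["p_value", "motif"], kind="stable")
            .reset_index(drop=True))


def read_motifs(path) -> list:
    """Read motifs from a simple text file.

    Two record styles may be mixed:

    * tab-separated lines ``name<TAB>IUPAC_consensus[<TAB>strand]``
    * PWM blocks starting ``>name threshold=<x> [strand=<both|forward>]``
      followed by four lines ``A|C|G|T v1 v2 ...``
    """
    motifs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if line.startswith(">"):
            header = line[1:].split()
            name = header[0]
            opts = dict(part.split("=", 1) for part in header[1:] if "=" in part)
            rows = {}
            for j in range(1, 5):
                base, *vals = lines[i + j].split()
                rows[base.rstrip(":").upper()] = [float(v) for v in vals]
            pwm = np.array([rows[b] for b in "ACGT"])
            motifs.append(Motif(name=name, pwm=pwm,
                                threshold=float(opts.get("threshold", 0.0)),
                                strand=opts.get("strand", "both")))
            i += 5
        else:
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed motif line: {line!r}")
            strand = parts[2] if len(parts) > 2 and parts[2] else "both"
            motifs.append(Motif(name=parts[0], consensus=parts[1], strand=strand))
            i += 1
    return motifs


@dataclass
class PromoterMotifAnalysis:
    """Estimator bundling promoter scanning and motif enrichment.

    ``fit`` builds the interaction matrix over the reference promoters and
    tests each retained motif for overrepresentation among the candidates.
    """

    prevalence_min: float = 0.05
    alpha: float = 0.05

    def get_params(self, deep: bool = True) -> dict:
        return {"prevalence_min": self.prevalence_min, "alpha": self.alpha}

    def set_params(self, **params) -> "PromoterMotifAnalysis":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, promoters: dict, motifs, candidate_genes,
            reference_genes=None) -> "PromoterMotifAnalysis":
        reference = list(reference_genes) if reference_genes is not None else sorted(promoters)
        # the interaction matrix (and its >5% prevalence rule) lives on the
        # candidate promoters; the reference is scanned separately to supply
        # the expected-by-chance hit frequencies
        self.matrix_ = build_interaction_matrix(promoters, motifs,
                                                genes=sorted(set(candidate_genes)),
                                                prevalence_min=self.prevalence_min)
        kept = [m for m in motifs if m.name in self.matrix_.hits.columns]
        scan_genes = sorted(set(reference) | set(candidate_genes))
        if kept:
            full = build_interaction_matrix(promoters, kept, genes=scan_genes,
                                            prevalence_min=-1.0)
            self.enrichment_ = tre_enrichment(full, candidate_genes,
                                              reference, alpha=self.alpha)
            self.significant_ = self.enrichment_.loc[
                self.enrichment_["significant"], "motif"].tolist()
        else:
            self.enrichment_ = tre_enrichment(self.matrix_, candidate_genes,
                                              reference, alpha=self.alpha)
            self.significant_ = []
        return self
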