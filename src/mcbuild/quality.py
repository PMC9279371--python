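"""Map-model quality scores at atom, residue, fragment and domain level.

The per-residue match score is the mean of the atom-level match scores over
the residue's available main-chain atoms.  Residue scores are aggregated
over continuous secondary-structure fragments and over domains, and blended:

    S'_fragment = 0.7 S_fragment + 0.3 S_domain
    S'_residue  = 0.7 S_residue  + 0.3 S_fragment

Blended residue scores are smoothed along the chain with a 1:2:4:8:16:8:4:2:1
window (truncated and renormalized at the termini).  A separate
no-superposition alignment score compares model fragments with a reference
in the shared map frame:

    alignment = (1/L) sum_i 1 / (1 + d_i^2 / d0^2),   d0 = 3.0 Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import StructureError
from .fitting import match_score
from .grid import ResolutionParams
from .probfield import MainChainPointSet
from .structure import ChainModel, write_complex

__all__ = [
    "QualityProfile", "AlignmentScore",
    "residue_scores", "fragment_scores", "smooth_residue_scores",
    "alignment_score", "write_quality_bfactors", "assign_ss_fallback",
    "quality_table",
]

SMOOTH_WEIGHTS = np.array([1, 2, 4, 8, 16, 8, 4, 2, 1], float)
ALIGNMENT_D0 = 3.0
MIN_FRAGMENT_REPORT_LEN = 5
BFACTOR_SENTINEL = 999.99
FRAGMENT_SCORE_THRESHOLD = -12.0   # reporting threshold for reliable fragments


@dataclass
class QualityProfile:
    """Per-residue quality scores for one placed chain."""

    chain_id: str
    residue_index: np.ndarray       # (n,)
    raw: np.ndarray                 # S_residue
    excluded: np.ndarray            # residues with no main-chain atoms
    fragment_id: Optional[np.ndarray] = None
    s_fragment: Optional[np.ndarray] = None     # per residue, its fragment's score
    s_domain: Optional[np.ndarray] = None
    blended_fragment: Optional[np.ndarray] = None
    blended_residue: Optional[np.ndarray] = None
    smoothed: Optional[np.ndarray] = None
    fragments: Optional[list] = None   # (fragment_id, ss, [residue indices]) of len >= 5

    def __len__(self) -> int:
        return len(self.residue_index)


@dataclass(frozen=True)
class AlignmentScore:
    L: int
    distances: np.ndarray
    value: float
    d0: float = ALIGNMENT_D0


def residue_scores(chain: ChainModel, Z: MainChainPointSet,
                   rp: ResolutionParams) -> QualityProfile:
    """Raw per-residue match scores of a placed chain.

    The score of a residue is the mean of its available main-chain atom
    scores; residues with no main-chain atoms are flagged excluded and get
    NaN.
    """
    tree = cKDTree(Z.points)
    idx = np.array([r.index for r in chain.residues])
    raw = np.full(len(chain), np.nan)
    excluded = np.zeros(len(chain), bool)
    for i, res in enumerate(chain.residues):
        atoms = res.main_chain()
        if not atoms:
            excluded[i] = True
            continue
        s = match_score(np.asarray(atoms), Z, rp, tree=tree, per_atom=True)
        raw[i] = float(np.mean(s))
    return QualityProfile(chain.chain_id, idx, raw, excluded)


def _fragment_runs(labels: Sequence[str]) -> np.ndarray:
    """Id of the maximal run of identical labels containing each residue."""
    ids = np.zeros(len(labels), int)
    fid = 0
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            fid += 1
        ids[i] = fid
    return ids


def fragment_scores(qp: QualityProfile, chain: ChainModel) -> QualityProfile:
    """Fragment/domain aggregation and the blended scores.

    Fragments are maximal runs of identical secondary-structure labels; all
    fragments get a score for blending, but only runs of at least
    5 residues enter the fragment-level report.
    """
    labels = [r.ss for r in chain.residues]
    frag_ids = _fragment_runs(labels)
    scored = ~qp.excluded
    s_fragment = np.full(len(qp), np.nan)
    for fid in np.unique(frag_ids):
        members = (frag_ids == fid) & scored
        if members.any():
            s_fragment[frag_ids == fid] = np.nanmean(qp.raw[members])
    s_domain = np.full(len(qp), np.nan)
    dom_ids = np.array([chain.domain_of(r.index).id for r in chain.residues])
    for did in np.unique(dom_ids):
        members = (dom_ids == did) & scored
        if members.any():
            s_domain[dom_ids == did] = np.nanmean(qp.raw[members])
    qp.fragment_id = frag_ids
    qp.s_fragment = s_fragment
    qp.s_domain = s_domain
    qp.blended_fragment = 0.7 * s_fragment + 0.3 * s_domain
    qp.blended_residue = 0.7 * qp.raw + 0.3 * s_fragment
    qp.smoothed = smooth_residue_scores(qp.blended_residue)
    qp.fragments = []
    for fid in np.unique(frag_ids):
        members = np.nonzero(frag_ids == fid)[0]
        if len(members) >= MIN_FRAGMENT_REPORT_LEN:
            qp.fragments.append((int(fid), labels[members[0]],
                                 [int(qp.residue_index[m]) for m in members]))
    return qp


def smooth_residue_scores(scores: np.ndarray) -> np.ndarray:
    """1:2:4:8:16:8:4:2:1 sliding-window smoothing along the chain.

    At the termini the window is truncated to the in-chain taps and the
    weights renormalized; NaN entries (excluded residues) are skipped the
    same way.
    """
    scores = np.asarray(scores, float)
    n = len(scores)
    out = np.full(n, np.nan)
    half = len(SMOOTH_WEIGHTS) // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = SMOOTH_WEIGHTS[lo - i + half: hi - i + half]
        vals = scores[lo:hi]
        ok = np.isfinite(vals)
        if ok.any():
            out[i] = float(np.sum(w[ok] * vals[ok]) / np.sum(w[ok]))
    return out


def alignment_score(model_ca: np.ndarray, ref_ca: np.ndarray,
                    d0: float = ALIGNMENT_D0) -> AlignmentScore:
    """No-superposition distance agreement between paired CA coordinates."""
    model_ca = np.atleast_2d(model_ca)
    ref_ca = np.atleast_2d(ref_ca)
    if model_ca.shape != ref_ca.shape:
        raise StructureError(
            f"fragment length mismatch: {len(model_ca)} vs {len(ref_ca)}")
    d = np.linalg.norm(model_ca - ref_ca, axis=1)
    value = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
    return AlignmentScore(len(d), d, value)


def assign_ss_fallback(chain: ChainModel) -> ChainModel:
    """Heuristic helix assignment when no external labels are available.

    Residues i..i+4 are labeled H whenever the CA(i)-CA(i+4) distance falls
    in the helical range (< 7 Å); everything else stays coil.
    """
    out = chain.copy()
    ca = {r.index: r.atoms.get("CA") for r in out.residues}
    order = [r.index for r in out.residues]
    helical = set()
    for i in range(len(order) - 4):
        a, b = ca[order[i]], ca[order[i + 4]]
        if a is not None and b is not None and np.linalg.norm(a - b) < 7.0:
            helical.update(order[i:i + 5])
    for r in out.residues:
        r.ss = "H" if r.index in helical else "C"
    return out


def quality_table(profiles: Sequence[QualityProfile]) -> pd.DataFrame:
    """Per-residue quality scores as a tidy table (TSV-ready)."""
    rows = []
    for qp in profiles:
        for i in range(len(qp)):
            rows.append({
                "chain": qp.chain_id,
                "residue": int(qp.residue_index[i]),
                "raw": qp.raw[i],
                "blended": (np.nan if qp.blended_residue is None
                            else qp.blended_residue[i]),
                "smoothed": (np.nan if qp.smoothed is None
                             else qp.smoothed[i]),
            })
    return pd.DataFrame(rows)


def write_quality_bfactors(chains: Sequence[ChainModel],
                           profiles: Sequence[QualityProfile],
                           path) -> None:
    """Write the model with smoothed residue scores in the B-factor column.

    Residues excluded from scoring get the sentinel 999.99.
    """
    bfactors = {}
    for ci, (chain, qp) in enumerate(zip(chains, profiles)):
        vals = qp.smoothed if qp.smoothed is not None else qp.raw
        for i in range(len(qp)):
            v = vals[i]
            bfactors[(ci, int(qp.residue_index[i]))] = (
                BFACTOR_SENTINEL if not np.isfinite(v) else float(v))
    write_complex(chains, path, bfactors=bfactors)
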