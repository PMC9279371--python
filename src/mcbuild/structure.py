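"""Chains, residues, domains: PDB I/O, pLDDT trimming, domain sidecars.

Conventions: coordinates in Å, residue indices are the (1-based) PDB
numbering and strictly increasing within a chain, each residue belongs to
exactly one domain.  Main-chain atoms are N, CA, C; a residue missing some of
them still contributes the ones it has to all scoring.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .errors import DomainError, StructureError

__all__ = [
    "Residue", "Domain", "ChainModel",
    "read_chains", "write_complex",
    "trim_by_plddt", "filter_short_chains",
    "load_domains", "parse_domain_sidecar", "read_ss_sidecar",
]

MAIN_CHAIN_ATOMS = ("N", "CA", "C")

_CHAIN_ID_POOL = (string.ascii_uppercase + string.ascii_lowercase
                  + string.digits)


@dataclass
class Residue:
    index: int                      # sequence position (PDB numbering)
    aa: str                         # one-letter code, 'X' if unknown
    atoms: dict                     # name -> (3,) ndarray, Å
    ss: str = "C"                   # secondary structure label H/E/C
    name3: str = "ALA"              # three-letter residue name for output
    flagged: bool = False           # unknown residue type retained

    def main_chain(self) -> list[np.ndarray]:
        return [self.atoms[a] for a in MAIN_CHAIN_ATOMS if a in self.atoms]


@dataclass
class Domain:
    id: int
    residue_ranges: list[tuple[int, int]]   # inclusive [start, end] indices

    def contains(self, index: int) -> bool:
        return any(lo <= index <= hi for lo, hi in self.residue_ranges)

    def n_residues(self, chain: "ChainModel") -> int:
        return sum(1 for r in chain.residues if self.contains(r.index))


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue]
    domains: list[Domain] = field(default_factory=list)
    plddt: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(
                f"chain {self.chain_id}: residue numbering not strictly "
                "increasing")
        if not self.domains:
            self.domains = [self._whole_chain_domain()]

    def _whole_chain_domain(self) -> Domain:
        if self.residues:
            return Domain(1, [(self.residues[0].index,
                               self.residues[-1].index)])
        return Domain(1, [])

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def main_chain_coords(self) -> np.ndarray:
        """(n, 3) coordinates of all available N/CA/C atoms, chain order."""
        coords = [a for r in self.residues for a in r.main_chain()]
        if not coords:
            raise StructureError(f"chain {self.chain_id} has no main-chain atoms")
        return np.asarray(coords)

    def ca_coords(self) -> np.ndarray:
        """(n_res, 3) CA coordinates; residues lacking CA are skipped."""
        return np.asarray([r.atoms["CA"] for r in self.residues
                           if "CA" in r.atoms])

    def domain_of(self, index: int) -> Domain:
        for d in self.domains:
            if d.contains(index):
                return d
        raise DomainError(
            f"chain {self.chain_id}: residue {index} not covered by any domain")

    def domain_main_chain_coords(self, domain_id: int) -> np.ndarray:
        dom = next(d for d in self.domains if d.id == domain_id)
        coords = [a for r in self.residues if dom.contains(r.index)
                  for a in r.main_chain()]
        return np.asarray(coords)

    def centroid(self) -> np.ndarray:
        return self.main_chain_coords().mean(axis=0)

    def copy(self) -> "ChainModel":
        residues = [Residue(r.index, r.aa,
                            {k: v.copy() for k, v in r.atoms.items()},
                            r.ss, r.name3, r.flagged)
                    for r in self.residues]
        domains = [Domain(d.id, list(d.residue_ranges)) for d in self.domains]
        plddt = None if self.plddt is None else self.plddt.copy()
        return ChainModel(self.chain_id, residues, domains, plddt)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "ChainModel":
        """Rigidly transformed copy: every atom mapped to R x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for r in out.residues:
            for name, pos in r.atoms.items():
                r.atoms[name] = R @ pos + t
        return out

    def fingerprint(self) -> tuple:
        """Hashable identity of sequence + geometry, for pose sharing
        between identical chain copies."""
        coords = np.round(self.main_chain_coords(), 3)
        return (self.sequence, coords.shape[0], coords.tobytes())


def _one_letter(name: str) -> tuple[str, bool]:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code, False
    return "X", True


def read_chains(path, bfactor_is_plddt: bool = False) -> list[ChainModel]:
    """Read a PDB (or mmCIF) file into one ChainModel per chain.

    Only the first model and the first conformer of alternate locations are
    used.  With ``bfactor_is_plddt`` the B-factor column is interpreted as
    per-residue pLDDT (AlphaFold convention, CA atom value).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read structure {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models in structure")
    chains: list[ChainModel] = []
    for ch in st[0]:
        residues = []
        plddt = []
        for res in ch:
            if res.is_water():
                continue
            atoms: dict = {}
            b_ca = None
            for atom in res:
                if atom.altloc not in ("", " ", "\0", "A"):
                    continue        # first conformer only
                if atom.name in atoms:
                    continue
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y,
                                             atom.pos.z])
                if atom.name == "CA":
                    b_ca = atom.b_iso
            if not atoms:
                continue
            aa, flagged = _one_letter(res.name)
            residues.append(Residue(res.seqid.num, aa, atoms,
                                    name3=res.name, flagged=flagged))
            plddt.append(b_ca if b_ca is not None
                         else next(iter(res)).b_iso)
        if not residues:
            continue
        chains.append(ChainModel(
            ch.name, residues,
            plddt=np.asarray(plddt, float) if bfactor_is_plddt else None))
    if not chains or all(len(c) == 0 for c in chains):
        raise StructureError(f"{path}: no protein atoms found")
    return chains


def write_complex(chains: Sequence[ChainModel], path,
                  bfactors: Optional[dict] = None) -> None:
    """Write placed chains as a multi-chain PDB with unique chain IDs.

    ``bfactors`` optionally maps ``(chain position, residue index)`` to the
    value written into the B-factor column (used for quality coloring).
    """
    if len(chains) > len(_CHAIN_ID_POOL):
        raise StructureError(
            f"cannot write {len(chains)} chains: PDB chain IDs limited to "
            f"{len(_CHAIN_ID_POOL)} without remapping")
    used: set[str] = set()
    st = gemmi.Structure()
    st.name = "mcbuild"
    model = gemmi.Model("1")
    for ci, chain in enumerate(chains):
        cid = chain.chain_id if (len(chain.chain_id) == 1
                                 and chain.chain_id not in used) else None
        if cid is None:
            cid = next(c for c in _CHAIN_ID_POOL if c not in used)
        used.add(cid)
        gch = gemmi.Chain(cid)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.index, " ")
            for name, pos in res.atoms.items():
                if not np.all(np.isfinite(pos)):
                    raise StructureError(
                        f"non-finite coordinates in chain {chain.chain_id} "
                        f"residue {res.index}")
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*pos)
                atom.element = gemmi.Element(name[:1])
                atom.occ = 1.0
                if bfactors is not None:
                    atom.b_iso = float(bfactors.get((ci, res.index), 999.99))
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def trim_by_plddt(c: ChainModel, cutoff: float = 50.0) -> ChainModel:
    """Drop maximal low-confidence runs from the chain termini.

    Continuous terminal stretches with pLDDT below ``cutoff`` are removed;
    interior low-confidence residues are kept.  The trimmed chain keeps a
    single whole-chain domain (segmentation should be loaded afterwards).
    """
    if c.plddt is None:
        raise StructureError(f"chain {c.chain_id}: no pLDDT values to trim by")
    ok = np.asarray(c.plddt) >= cutoff
    if not ok.any():
        raise StructureError(
            f"chain {c.chain_id}: trimming at pLDDT {cutoff} removes every "
            "residue")
    first = int(np.argmax(ok))
    last = int(len(ok) - 1 - np.argmax(ok[::-1]))
    out = c.copy()
    out.residues = out.residues[first:last + 1]
    out.plddt = out.plddt[first:last + 1]
    out.domains = [out._whole_chain_domain()]
    return out


def filter_short_chains(chains: Iterable[ChainModel],
                        min_len: int = 20) -> list[ChainModel]:
    """Discard chains shorter than ``min_len`` residues."""
    return [c for c in chains if len(c) >= min_len]


def parse_domain_sidecar(text: str) -> list[list[list[tuple[int, int]]]]:
    """Parse candidate domain assignments from sidecar text.

    One assignment per line; domains separated by ``;``; each domain is a
    comma-joined list of 1-based inclusive ranges ``start-end``.
    """
    assignments = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        domains = []
        for dom in line.split(";"):
            ranges = []
            for rng in dom.split(","):
                lo, hi = rng.strip().split("-")
                lo, hi = int(lo), int(hi)
                if hi < lo:
                    raise DomainError(f"invalid range {rng!r} in sidecar")
                ranges.append((lo, hi))
            domains.append(ranges)
        assignments.append(domains)
    if not assignments:
        raise DomainError("domain sidecar contains no assignments")
    return assignments


def _validate_partition(c: ChainModel, domains: list[Domain]) -> None:
    seen: dict[int, int] = {}
    for d in domains:
        for r in c.residues:
            if d.contains(r.index):
                if r.index in seen:
                    raise DomainError(
                        f"chain {c.chain_id}: residue {r.index} in domains "
                        f"{seen[r.index]} and {d.id} (overlap)")
                seen[r.index] = d.id
    missing = [r.index for r in c.residues if r.index not in seen]
    if missing:
        raise DomainError(
            f"chain {c.chain_id}: residues not covered by any domain "
            f"(first: {missing[0]})")


def load_domains(c: ChainModel, path=None, n_splits: Optional[int] = None,
                 min_domain_size: int = 30) -> ChainModel:
    """Attach a domain segmentation to the chain.

    With a sidecar file (external segmentation output, several candidate
    assignments), the assignment with the most domains subject to every
    domain holding at least ``min_domain_size`` residues is selected; if no
    candidate satisfies the size constraint the candidate with the fewest
    domains is used.  Without a sidecar the chain is either kept as one
    domain or, when ``n_splits`` is set, cut into equal contiguous splits of
    at least ``min_domain_size`` residues.
    """
    out = c.copy()
    if path is not None:
        with open(path) as fh:
            candidates = parse_domain_sidecar(fh.read())
        sizes = []
        for cand in candidates:
            doms = [Domain(i + 1, ranges) for i, ranges in enumerate(cand)]
            _validate_partition(out, doms)
            sizes.append([d.n_residues(out) for d in doms])
        eligible = [i for i, sz in enumerate(sizes)
                    if all(s >= min_domain_size for s in sz)]
        if eligible:
            best = max(eligible, key=lambda i: len(sizes[i]))
        else:
            best = min(range(len(candidates)), key=lambda i: len(sizes[i]))
        out.domains = [Domain(i + 1, ranges)
                       for i, ranges in enumerate(candidates[best])]
        return out
    if n_splits is None or n_splits <= 1 or len(out) < 2 * min_domain_size:
        out.domains = [out._whole_chain_domain()]
        return out
    n_splits = min(n_splits, len(out) // min_domain_size)
    bounds = np.linspace(0, len(out), n_splits + 1).round().astype(int)
    domains = []
    for i in range(n_splits):
        lo = out.residues[bounds[i]].index
        hi = out.residues[bounds[i + 1] - 1].index
        domains.append(Domain(i + 1, [(lo, hi)]))
    out.domains = domains
    return out


def read_ss_sidecar(c: ChainModel, path) -> ChainModel:
    """Attach secondary-structure labels (one H/E/C label per residue line)."""
    labels = [ln.strip().upper() for ln in open(path) if ln.strip()]
    if len(labels) != len(c):
        raise StructureError(
            f"secondary-structure sidecar has {len(labels)} labels for "
            f"{len(c)} residues")
    out = c.copy()
    for res, lab in zip(out.residues, labels):
        res.ss = lab if lab in ("H", "E") else "C"
    return out
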