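"""Role-annotated topology model.

An :class:`AnnotatedSystem` holds the per-atom record arrays of a topology
plus the role index sets every downstream statistic needs: gold-core atoms,
ligand chains with their cationic headgroups, hydrogen-bond donor triplets
classified by guanidinium position (the two terminal eta nitrogens vs the
linking epsilon nitrogen), acceptor sets, pseudo-lipid P/N sites with tail
chains, counterions and waters.

Roles are assigned from a small declarative config (typically YAML) mapping
residue/atom-name patterns to roles; see :func:`annotate`.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field

import numpy as np

DONOR_CLASSES = ("eta", "epsilon", "other")
ACCEPTOR_CLASSES = ("water", "phosphate", "other")


class AnnotationError(ValueError):
    """A roles config that cannot be applied to the topology."""


@dataclass(frozen=True)
class DonorTriplet:
    """A donor heavy atom with its bonded hydrogens and donor class."""

    heavy: int
    hydrogens: tuple[int, ...]
    donor_class: str = "other"


@dataclass(frozen=True)
class Ligand:
    """One anchored chain, atoms ordered anchor -> headgroup."""

    atoms: tuple[int, ...]
    headgroup: tuple[int, ...]
    head_rep: int  # representative (central) headgroup atom


@dataclass(frozen=True)
class Lipid:
    """A pseudo-lipid with one phosphorus and one nitrogen site."""

    resid: int
    p_site: int
    n_site: int
    tails: tuple[tuple[int, ...], ...] = ()


@dataclass
class AnnotatedSystem:
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    elements: np.ndarray
    core_atoms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    ligands: list[Ligand] = field(default_factory=list)
    donors: list[DonorTriplet] = field(default_factory=list)
    acceptors: dict[str, np.ndarray] = field(default_factory=dict)
    lipids: list[Lipid] = field(default_factory=list)
    waters: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    counterions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def headgroup_atoms(self) -> np.ndarray:
        if not self.ligands:
            return np.empty(0, dtype=int)
        return np.concatenate([np.asarray(l.headgroup, dtype=int) for l in self.ligands])

    @property
    def head_reps(self) -> np.ndarray:
        return np.asarray([l.head_rep for l in self.ligands], dtype=int)

    @property
    def lipid_p_sites(self) -> np.ndarray:
        return np.asarray([l.p_site for l in self.lipids], dtype=int)

    @property
    def lipid_n_sites(self) -> np.ndarray:
        return np.asarray([l.n_site for l in self.lipids], dtype=int)

    def molecules(self) -> list[np.ndarray]:
        """Atom index groups treated as whole molecules (one per residue)."""
        order = np.arange(self.n_atoms)
        groups: list[np.ndarray] = []
        # residues are contiguous in file order; split on resid change
        change = np.nonzero(np.diff(self.resids))[0] + 1
        for g in np.split(order, change):
            groups.append(g)
        return groups

    def role_counts(self) -> dict[str, int]:
        counts = {
            "core": int(self.core_atoms.size),
            "ligands": len(self.ligands),
            "headgroup_atoms": int(self.headgroup_atoms.size),
            "donors": len(self.donors),
            "lipids": len(self.lipids),
            "waters": int(self.waters.size),
            "counterions": int(self.counterions.size),
        }
        for cls, idx in self.acceptors.items():
            counts[f"acceptors_{cls}"] = int(np.asarray(idx).size)
        assigned = set(self.core_atoms.tolist()) | set(self.waters.tolist()) | set(
            self.counterions.tolist()
        )
        for l in self.ligands:
            assigned.update(l.atoms)
        for lp in self.lipids:
            assigned.add(lp.p_site)
            assigned.add(lp.n_site)
            for t in lp.tails:
                assigned.update(t)
        counts["other"] = self.n_atoms - len(assigned)
        return counts


def _match(values: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean mask of ``values`` matching a (glob) pattern."""
    if any(c in pattern for c in "*?["):
        return np.asarray([fnmatch.fnmatchcase(v, pattern) for v in values])
    return values == pattern


def annotate(
    names,
    resnames,
    resids,
    roles_config: dict,
    elements=None,
) -> AnnotatedSystem:
    """Build an :class:`AnnotatedSystem` from atom records and a roles config.

    The config is a mapping with (all optional) keys::

        core:        {resname: AUC}
        ligands:     {resname: LIG, headgroup_atoms: [CZ, ...], headgroup_center: CZ}
        donors:      [{resname: LIG, atom: NH1, hydrogens: [HH11, HH12], class: eta}, ...]
        acceptors:   {water: [{resname: SOL, atom: OW}], phosphate: [...]}
        lipids:      {resname: PC, p_atom: P, n_atom: N, tails: [[C1A, ...], ...]}
        waters:      {resname: SOL}
        counterions: {resname: CL}

    Patterns may use shell globs. A pattern matching zero atoms emits a
    warning; a lipid residue missing its P or N site raises
    :class:`AnnotationError` naming the residue.
    """
    names = np.asarray(names, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    resids = np.asarray(resids, dtype=int)
    if elements is None:
        elements = np.asarray([n.strip("0123456789")[:1] or "X" for n in names], dtype=object)
    else:
        elements = np.asarray(elements, dtype=object)
    sys_ = AnnotatedSystem(names=names, resnames=resnames, resids=resids, elements=elements)
    cfg = roles_config or {}

    def resmask(resname_pat):
        m = _match(resnames, resname_pat)
        if not m.any():
            warnings.warn(f"role pattern matched zero atoms: resname {resname_pat!r}")
        return m

    if "core" in cfg:
        sys_.core_atoms = np.nonzero(resmask(cfg["core"]["resname"]))[0]

    name_index: dict[tuple[int, str], int] = {}

    def residue_atoms(mask):
        """Yield (resid, index array) for each residue under the mask."""
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            return
        split = np.nonzero(np.diff(resids[idx]))[0] + 1
        for g in np.split(idx, split):
            yield int(resids[g[0]]), g

    if "ligands" in cfg:
        lcfg = cfg["ligands"]
        head_names = set(lcfg.get("headgroup_atoms", []))
        center = lcfg.get("headgroup_center")
        for resid, g in residue_atoms(resmask(lcfg["resname"])):
            head = tuple(int(i) for i in g if names[i] in head_names)
            if not head:
                raise AnnotationError(
                    f"ligand residue {resid} has no headgroup atoms {sorted(head_names)}"
                )
            reps = [i for i in head if names[i] == center]
            rep = reps[0] if reps else head[0]
            sys_.ligands.append(Ligand(atoms=tuple(int(i) for i in g), headgroup=head, head_rep=rep))
            for i in g:
                name_index[(resid, names[i])] = int(i)

    if "donors" in cfg:
        for dcfg in cfg["donors"]:
            dcls = dcfg.get("class", "other")
            if dcls not in DONOR_CLASSES:
                raise AnnotationError(f"unknown donor class {dcls!r}")
            mask = resmask(dcfg["resname"]) & _match(names, dcfg["atom"])
            for heavy in np.nonzero(mask)[0]:
                resid = int(resids[heavy])
                hyds = []
                for hname in dcfg["hydrogens"]:
                    key = (resid, hname)
                    if key in name_index:
                        hyds.append(name_index[key])
                    else:
                        cand = np.nonzero((resids == resid) & (names == hname))[0]
                        if cand.size == 0:
                            raise AnnotationError(
                                f"donor {dcfg['atom']} in residue {resid}: missing hydrogen {hname}"
                            )
                        hyds.append(int(cand[0]))
                sys_.donors.append(
                    DonorTriplet(heavy=int(heavy), hydrogens=tuple(hyds), donor_class=dcls)
                )

    if "acceptors" in cfg:
        for acls, patterns in cfg["acceptors"].items():
            if acls not in ACCEPTOR_CLASSES:
                raise AnnotationError(f"unknown acceptor class {acls!r}")
            idx_parts = []
            for p in patterns:
                mask = resmask(p["resname"]) & _match(names, p["atom"])
                idx_parts.append(np.nonzero(mask)[0])
            sys_.acceptors[acls] = (
                np.unique(np.concatenate(idx_parts)) if idx_parts else np.empty(0, dtype=int)
            )

    if "lipids" in cfg:
        lcfg = cfg["lipids"]
        tails_cfg = lcfg.get("tails", [])
        for resid, g in residue_atoms(resmask(lcfg["resname"])):
            local = {names[i]: int(i) for i in g}
            p = local.get(lcfg["p_atom"])
            n = local.get(lcfg["n_atom"])
            if p is None or n is None:
                missing = lcfg["p_atom"] if p is None else lcfg["n_atom"]
                raise AnnotationError(
                    f"lipid residue {resid} is missing its {missing} site"
                )
            tails = []
            for chain in tails_cfg:
                beads = tuple(local[a] for a in chain if a in local)
                if beads:
                    tails.append(beads)
            sys_.lipids.append(Lipid(resid=resid, p_site=p, n_site=n, tails=tuple(tails)))

    if "waters" in cfg:
        sys_.waters = np.nonzero(resmask(cfg["waters"]["resname"]))[0]
    if "counterions" in cfg:
        sys_.counterions = np.nonzero(resmask(cfg["counterions"]["resname"]))[0]
    return sys_


# ---------------------------------------------------------------------------
# Selection expressions
# ---------------------------------------------------------------------------

_ROLE_KEYWORDS = (
    "core",
    "headgroup",
    "ligand",
    "lipid",
    "water",
    "counterion",
    "phosphate",
    "donor",
)


def _role_indices(system: AnnotatedSystem, role: str) -> np.ndarray:
    if role == "core":
        return system.core_atoms
    if role == "headgroup":
        return system.headgroup_atoms
    if role == "ligand":
        parts = [np.asarray(l.atoms, dtype=int) for l in system.ligands]
        return np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=int)
    if role == "lipid":
        parts = []
        for lp in system.lipids:
            parts.append([lp.p_site, lp.n_site])
            parts.extend(lp.tails)
        return (
            np.unique(np.concatenate([np.asarray(p, dtype=int) for p in parts]))
            if parts
            else np.empty(0, dtype=int)
        )
    if role == "water":
        return system.waters
    if role == "counterion":
        return system.counterions
    if role == "phosphate":
        return np.asarray(system.acceptors.get("phosphate", np.empty(0, dtype=int)))
    if role == "donor":
        return np.unique([d.heavy for d in system.donors]) if system.donors else np.empty(0, dtype=int)
    raise ValueError(f"unknown role keyword {role!r}")


class _Parser:
    """Recursive-descent parser for the tiny selection grammar:

    expr    := term (("or") term)*
    term    := factor (("and") factor)*
    factor  := "not" factor | "(" expr ")" | primary
    primary := "resname" PAT | "name" PAT | "role" KEYWORD | "index" i[:j]
    """

    def __init__(self, text: str, system: AnnotatedSystem):
        self.tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        self.pos = 0
        self.system = system

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in selection: {self.tokens[self.pos:]}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise ValueError("unbalanced parenthesis in selection")
            return mask
        return self.primary()

    def primary(self):
        sys_ = self.system
        key = self.take()
        if key is None:
            raise ValueError("empty selection expression")
        if key == "resname":
            return _match(sys_.resnames, self.take())
        if key == "name":
            return _match(sys_.names, self.take())
        if key == "role":
            mask = np.zeros(sys_.n_atoms, dtype=bool)
            mask[_role_indices(sys_, self.take())] = True
            return mask
        if key == "index":
            spec = self.take()
            mask = np.zeros(sys_.n_atoms, dtype=bool)
            if ":" in spec:
                lo, hi = spec.split(":")
                mask[int(lo) : int(hi)] = True
            else:
                mask[int(spec)] = True
            return mask
        raise ValueError(f"unknown selection keyword {key!r}")


def select(system: AnnotatedSystem, expression: str) -> np.ndarray:
    """Resolve a selection expression into a sorted array of atom indices.

    Grammar: ``resname PAT | name PAT | role KEYWORD | index i[:j]`` combined
    with ``and``/``or``/``not`` and parentheses. Resolution is deterministic:
    the same expression on the same system always yields the same indices.
    """
    mask = _Parser(expression, system).parse()
    return np.nonzero(mask)[0]
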