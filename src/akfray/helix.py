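"""Helix geometry between two structural states of a protein.

Quantifies the plasticity of an alpha-helix across a conformational
transition: per-residue helicity from backbone hydrogen bonding
(Kabsch-Sander electrostatic energy, cutoff -0.5 kcal/mol), a helix axis
fitted through local helix-center points, least-squares (Kabsch)
superposition of the rigid core, and from these the tilt angle, the
spatial translation of the helix, terminal fraying, and bend angles.

Structures are plain nested containers (chain -> residue -> atoms) read
from PDB/mmCIF via gemmi; author residue numbering is kept throughout and
the first model of multi-model files is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Residue",
    "StructureModel",
    "HelixAxis",
    "HelixComparison",
    "read_structure",
    "write_pdb",
    "place_atom",
    "build_backbone",
    "assign_helicity",
    "fit_axis",
    "helix_centers",
    "superpose",
    "compare_helix",
    "bend_angle",
]

HBOND_CUTOFF_KCAL = -0.5

# ideal backbone internal coordinates (A, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8

PHI_HELIX, PSI_HELIX = -57.0, -47.0
PHI_EXT, PSI_EXT = -120.0, 120.0


@dataclass
class Residue:
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclass
class StructureModel:
    """Coordinates of one model: chains -> author residue number -> atoms."""

    chains: dict[str, dict[int, Residue]] = field(default_factory=dict)
    pdb_id: str = ""
    model_number: int = 1

    def chain(self, chain_id: str | None = None) -> dict[int, Residue]:
        if chain_id is None:
            chain_id = next(iter(self.chains))
        return self.chains[chain_id]

    def copy(self) -> "StructureModel":
        out = StructureModel(pdb_id=self.pdb_id, model_number=self.model_number)
        for cid, residues in self.chains.items():
            out.chains[cid] = {
                num: Residue(r.name, {a: xyz.copy() for a, xyz in r.atoms.items()})
                for num, r in residues.items()
            }
        return out

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = self.copy()
        for residues in out.chains.values():
            for r in residues.values():
                for a in r.atoms:
                    r.atoms[a] = rotation @ r.atoms[a] + translation
        return out


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file (first model, polymer ATOM records)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    out = StructureModel(pdb_id=st.name, model_number=1)
    for chain in model:
        residues: dict[int, Residue] = {}
        for res in chain:
            if res.het_flag == "H" and not res.is_amino_acid():
                continue
            r = Residue(res.name)
            for atom in res:
                r.atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            residues[res.seqid.num] = r
        if residues:
            out.chains[chain.name] = residues
    return out


def write_pdb(model: StructureModel, path: str | Path) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = model.pdb_id or "XXXX"
    gmodel = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for num in sorted(residues):
            res = residues[num]
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(num, " ")
            for aname, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(aname[0])
                atom.pos = gemmi.Position(*xyz)
                gres.add_atom(atom)
            chain.add_residue(gres)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)


# ---------------------------------------------------------------------------
# Backbone construction (NeRF)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |cd|=bond, angle(b,c,d), dihedral(a,b,c,d)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: list[tuple[float, float]], first_residue: int = 1, chain_id: str = "A"
) -> StructureModel:
    """Build an all-backbone (N, CA, C, O) chain from per-residue phi/psi.

    phi of the first residue and psi of the last have no structural effect
    beyond the terminal carbonyl; omega is fixed trans (180 deg). Residue
    names are ALA.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need >= 2 residues")
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    O = [None] * n_res
    N[0] = np.zeros(3)
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANG_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANG_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANG_C_N_CA, 180.0)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANG_N_CA_C, phi_psi[i][0])
        O[i - 1] = place_atom(
            N[i - 1], CA[i - 1], C[i - 1], BOND_C_O, ANG_CA_C_O, psi_prev + 180.0
        )
    O[n_res - 1] = place_atom(
        N[-1], CA[-1], C[-1], BOND_C_O, ANG_CA_C_O, phi_psi[-1][1] + 180.0
    )
    model = StructureModel()
    model.chains[chain_id] = {
        first_residue
        + i: Residue("ALA", {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]})
        for i in range(n_res)
    }
    return model


# ---------------------------------------------------------------------------
# Helicity assignment (backbone H-bond energies)


def _amide_h(residues: dict[int, Residue], num: int) -> np.ndarray | None:
    """Amide proton position: stored H if present, else built 1.0 A from N
    along the direction of the preceding carbonyl C->O bond reversed."""
    res = residues[num]
    if "H" in res.atoms:
        return res.atoms["H"]
    prev = residues.get(num - 1)
    if prev is None or "C" not in prev.atoms or "O" not in prev.atoms:
        return None
    if "N" not in res.atoms:
        return None
    d = prev.atoms["C"] - prev.atoms["O"]
    d = d / np.linalg.norm(d)
    return res.atoms["N"] + d


def hbond_energy(
    acceptor: Residue, donor_n: np.ndarray, donor_h: np.ndarray
) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol) of C=O ... H-N."""
    c = acceptor.atoms["C"]
    o = acceptor.atoms["O"]
    d_on = np.linalg.norm(o - donor_n)
    d_ch = np.linalg.norm(c - donor_h)
    d_oh = np.linalg.norm(o - donor_h)
    d_cn = np.linalg.norm(c - donor_n)
    if min(d_on, d_ch, d_oh, d_cn) < 0.5:
        return -9.9  # clash guard, as in the original algorithm
    return 0.084 * 332.0 * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)


def assign_helicity(
    model: StructureModel,
    chain_id: str | None = None,
    residue_range: tuple[int, int] | None = None,
) -> dict[int, str]:
    """Per-residue helicity status over a chain (or an explicit range).

    A residue is "helical" when it participates in an i->i+4 backbone
    hydrogen bond (as acceptor via its carbonyl, or as donor via its amide)
    with Kabsch-Sander energy below -0.5 kcal/mol. Residues absent from the
    model within the requested range are "unmodeled"; residues flanking a
    chain break are "unassessable".
    """
    residues = model.chain(chain_id)
    if residue_range is None:
        lo, hi = min(residues), max(residues)
    else:
        lo, hi = residue_range
    nums = list(range(lo, hi + 1))

    status: dict[int, str] = {}
    breaks: set[int] = set()
    for num in nums:
        if num not in residues or not residues[num].has_backbone():
            status[num] = "unmodeled"
            continue
        nxt = residues.get(num + 1)
        if nxt is not None and "C" in residues[num].atoms and "N" in nxt.atoms:
            if np.linalg.norm(nxt.atoms["N"] - residues[num].atoms["C"]) > 2.0:
                breaks.add(num)
                breaks.add(num + 1)
        status[num] = "non-helical"

    def bonded(i_acc: int, i_don: int) -> bool:
        acc = residues.get(i_acc)
        don = residues.get(i_don)
        if acc is None or don is None:
            return False
        if "C" not in acc.atoms or "O" not in acc.atoms or "N" not in don.atoms:
            return False
        h = _amide_h(residues, i_don)
        if h is None:
            return False
        return hbond_energy(acc, don.atoms["N"], h) < HBOND_CUTOFF_KCAL

    for num in nums:
        if status[num] == "unmodeled":
            continue
        if bonded(num, num + 4) or bonded(num - 4, num):
            status[num] = "helical"
    for num in breaks:
        if num in status and status[num] != "unmodeled":
            status[num] = "unassessable"
    return status


# ---------------------------------------------------------------------------
# Axis fitting and superposition


@dataclass
class HelixAxis:
    anchor: np.ndarray  # centroid of the helix-center points (lies on the axis)
    direction: np.ndarray  # unit vector, oriented N -> C
    goodness: float  # RMS distance of center points to the axis, A
    centers: np.ndarray


def helix_centers(ca: np.ndarray) -> np.ndarray:
    """Local helix-center points: mean of 4 consecutive CA positions.

    Center i averages CA[i-1..i+2]; one turn of an ideal helix averages
    out the radial component almost exactly, leaving points on the axis.
    """
    ca = np.asarray(ca, float)
    if len(ca) < 4:
        raise ValueError("need >= 4 CA positions")
    return np.array([ca[i - 1 : i + 3].mean(axis=0) for i in range(1, len(ca) - 2)])


def fit_axis(ca: np.ndarray, min_ca: int = 8) -> HelixAxis:
    """Principal axis through the local helix-center points of >= 8 CA.

    min_ca can be relaxed (to >= 6) for the short sub-segments of bend-angle
    fitting; below 6 CA the center points no longer define a stable line.
    """
    ca = np.asarray(ca, float)
    if len(ca) < max(min_ca, 6):
        raise ValueError(f"need >= {max(min_ca, 6)} consecutive CA positions for an axis")
    pts = helix_centers(ca)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ (pts[-1] - pts[0]) < 0:
        direction = -direction
    proj = centered @ direction
    perp = centered - np.outer(proj, direction)
    goodness = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return HelixAxis(anchor=centroid, direction=direction, goodness=goodness, centers=pts)


MAINCHAIN = ("N", "CA", "C", "O")


def _paired_coords(
    mobile: StructureModel,
    target: StructureModel,
    residue_range: tuple[int, int],
    chain_id: str | None,
    atoms=MAINCHAIN,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    rm = mobile.chain(chain_id)
    rt = target.chain(chain_id)
    xs, ys, missing = [], [], []
    for num in range(residue_range[0], residue_range[1] + 1):
        for a in atoms:
            ok = num in rm and a in rm[num].atoms and num in rt and a in rt[num].atoms
            if ok:
                xs.append(rm[num].atoms[a])
                ys.append(rt[num].atoms[a])
            else:
                missing.append((num, a))
    return np.array(xs), np.array(ys), missing


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    residue_range: tuple[int, int],
    chain_id: str | None = None,
    atoms=MAINCHAIN,
) -> tuple[np.ndarray, np.ndarray, float, list[tuple[int, str]]]:
    """Kabsch least-squares superposition of mobile onto target.

    Returns (rotation, translation, rmsd, missing_pairs); the proper
    rotation (det = +1) minimizing the RMSD over the paired atoms.
    """
    x, y, missing = _paired_coords(mobile, target, residue_range, chain_id, atoms)
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired atoms, got {len(x)}")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    moved = (rot @ x.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rot, trans, rmsd, missing


@dataclass
class HelixComparison:
    tilt_deg: float
    translation_ang: float
    frayed_n_terminal: list[int]
    frayed_c_terminal: list[int]
    bend_change_deg: float
    core_rmsd_ang: float
    common_folded: tuple[int, int]
    metadata: dict = field(default_factory=dict)


def _longest_run(nums: list[int]) -> list[int]:
    best, cur = [], []
    for n in sorted(nums):
        if cur and n == cur[-1] + 1:
            cur.append(n)
        else:
            cur = [n]
        if len(cur) > len(best):
            best = cur
    return best


def _ca_array(residues: dict[int, Residue], nums: list[int]) -> np.ndarray:
    return np.array([residues[n].atoms["CA"] for n in nums])


def compare_helix(
    state_a: StructureModel,
    state_b: StructureModel,
    helix_range: tuple[int, int],
    core_range: tuple[int, int],
    chain_id: str | None = None,
) -> HelixComparison:
    """Tilt, translation and fraying of a helix between two states.

    State B is superposed onto state A over the main-chain atoms of the
    core range; helix axes are then fitted to the common folded part of the
    helix (residues helical and modeled in both states) and compared. The
    translation is the distance between the axis anchor points (centroids
    of the helix-center points over the same residue window). Termini
    helical in one state but non-helical or unmodeled in the other are
    reported as frayed.
    """
    rot, trans, core_rmsd, _ = superpose(state_b, state_a, core_range, chain_id)
    b_on_a = state_b.transform(rot, trans)

    hel_a = assign_helicity(state_a, chain_id, helix_range)
    hel_b = assign_helicity(b_on_a, chain_id, helix_range)
    folded_a = {n for n, s in hel_a.items() if s == "helical"}
    folded_b = {n for n, s in hel_b.items() if s == "helical"}
    common = _longest_run(sorted(folded_a & folded_b))
    if len(common) < 8:
        raise ValueError(
            f"common folded helix segment too short ({len(common)} residues) in "
            f"range {helix_range}"
        )

    ra = state_a.chain(chain_id)
    rb = b_on_a.chain(chain_id)
    axis_a = fit_axis(_ca_array(ra, common))
    axis_b = fit_axis(_ca_array(rb, common))
    cosang = float(np.clip(axis_a.direction @ axis_b.direction, -1.0, 1.0))
    tilt = math.degrees(math.acos(cosang))
    translation = float(np.linalg.norm(axis_a.anchor - axis_b.anchor))

    lo, hi = helix_range
    frayed_n, frayed_c = [], []
    for n in range(lo, hi + 1):
        if hel_a.get(n) == "helical" and hel_b.get(n) in ("non-helical", "unmodeled"):
            frayed_n.append(n)
        else:
            break
    for n in range(hi, lo - 1, -1):
        if hel_a.get(n) == "helical" and hel_b.get(n) in ("non-helical", "unmodeled"):
            frayed_c.append(n)
        else:
            break
    frayed_c = sorted(frayed_c)

    bend_change = float("nan")
    if len(common) >= 13:
        mid = common[len(common) // 2]
        try:
            ba = bend_angle(state_a, (common[0], common[-1]), mid, chain_id)
            bb = bend_angle(b_on_a, (common[0], common[-1]), mid, chain_id)
            bend_change = bb - ba
        except ValueError:
            pass

    return HelixComparison(
        tilt_deg=tilt,
        translation_ang=translation,
        frayed_n_terminal=frayed_n,
        frayed_c_terminal=frayed_c,
        bend_change_deg=bend_change,
        core_rmsd_ang=core_rmsd,
        common_folded=(common[0], common[-1]),
        metadata={
            "translation_definition": "distance between axis anchor points "
            "(centroids of helix-center points of the common folded segment) "
            "after core superposition",
            "core_range": core_range,
            "helix_range": helix_range,
        },
    )


def bend_angle(
    model: StructureModel,
    segment: tuple[int, int],
    split: int,
    chain_id: str | None = None,
) -> float:
    """Angle (deg) between axes fitted to the two halves of a helix at split."""
    residues = model.chain(chain_id)
    lo, hi = segment
    n_side = [n for n in range(lo, split + 1) if n in residues]
    c_side = [n for n in range(split, hi + 1) if n in residues]
    if len(n_side) < 6 or len(c_side) < 6:
        raise ValueError("need >= 6 residues on each side of the split")
    ax_n = fit_axis(_ca_array(residues, n_side), min_ca=6)
    ax_c = fit_axis(_ca_array(residues, c_side), min_ca=6)
    cosang = float(np.clip(ax_n.direction @ ax_c.direction, -1.0, 1.0))
    return math.degrees(math.acos(cosang))
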