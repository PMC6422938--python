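"""Twin/sibling pedigrees, the expected-genetic-covariance matrix, and its
eigendecomposition.

The central object is the relatedness matrix ``2Φ`` over phenotyped
individuals, where ``Φ`` is the kinship matrix of pairwise kinship
coefficients.  Under the additive polygenic model the phenotypic covariance
of a pedigree is ``Ω = 2Φ·σg² + I·σe²``, so storing the doubled kinship
(the covariance *multiplier*) avoids factor-of-two mistakes downstream:
an MZ co-twin pair has entry 1, DZ co-twins / full siblings 0.5,
parent–offspring 0.5, unrelated individuals 0.

Monozygotic co-twins are genetically identical: every member of an
``mz_group`` is given the genome of a single representative, so co-twins
have relatedness 1 to each other and identical relatedness to everyone
else.

Kinship coefficients are computed by the standard recursion over a
generation-ordered pedigree: founders are mutually unrelated with
self-kinship ½; for a non-founder *i* and any *j* that is not a descendant
of *i*, ``φ(i,j) = ½(φ(father_i, j) + φ(mother_i, j))`` and
``φ(i,i) = ½(1 + φ(father_i, mother_i))``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PedigreeError, ValidationError

__all__ = [
    "Pedigree",
    "RelatednessMatrix",
    "KinshipEigen",
    "compute_relatedness",
    "make_twin_pedigree",
    "eigendecompose",
    "read_pedigree_csv",
    "write_pedigree_csv",
]

_SEX_CANON = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
}

_EIG_TOL = 1e-8


@dataclass(frozen=True)
class Pedigree:
    """A validated pedigree table.

    ``table`` columns: ``id``, ``father``, ``mother`` (empty string for a
    founder), ``sex`` ({'male','female'}), ``mz_group`` (empty string when
    not an MZ twin; individuals sharing a non-empty label are monozygotic
    co-twins), ``family`` and boolean ``phenotyped``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _validate(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def phenotyped_ids(self) -> list[str]:
        return list(self.table.loc[self.table["phenotyped"], "id"])

    def __len__(self) -> int:
        return len(self.table)

    def with_phenotyped(self, ids) -> "Pedigree":
        """Return a copy with the phenotyped flag set from ``ids``."""
        ids = set(ids)
        unknown = ids - set(self.table["id"])
        if unknown:
            raise PedigreeError(f"phenotyped ids not in pedigree: {sorted(unknown)[:5]}")
        tab = self.table.copy()
        tab["phenotyped"] = tab["id"].isin(ids)
        return Pedigree(tab)


def _validate(tab: pd.DataFrame) -> None:
    required = {"id", "father", "mother", "sex", "mz_group", "family", "phenotyped"}
    missing = required - set(tab.columns)
    if missing:
        raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
    ids = list(tab["id"])
    if len(set(ids)) != len(ids):
        raise PedigreeError("duplicate individual ids")
    known = set(ids)
    rows = {r.id: r for r in tab.itertuples(index=False)}
    for r in tab.itertuples(index=False):
        for par in (r.father, r.mother):
            if par and par not in known:
                raise PedigreeError(f"{r.id}: parent {par!r} not in pedigree")
        if bool(r.father) != bool(r.mother):
            raise PedigreeError(f"{r.id}: exactly one parent recorded; need both or neither")
        if r.sex not in ("male", "female"):
            raise PedigreeError(f"{r.id}: bad sex {r.sex!r}")
    # acyclicity via iterative depth assignment (also yields generation order)
    _generation_depths(rows)
    # MZ groups share both parents and family
    for label, grp in tab[tab["mz_group"] != ""].groupby("mz_group"):
        if grp["father"].nunique() != 1 or grp["mother"].nunique() != 1:
            raise PedigreeError(f"mz_group {label!r}: co-twins do not share both parents")
        if grp["family"].nunique() != 1:
            raise PedigreeError(f"mz_group {label!r}: co-twins span families")
        if (grp["father"] == "").any():
            raise PedigreeError(f"mz_group {label!r}: founders cannot be MZ twins")


def _generation_depths(rows: dict) -> dict:
    """Depth of each individual above its founders; raises on parent cycles."""
    depth: dict = {}

    def visit(i: str, stack: tuple) -> int:
        if i in depth:
            return depth[i]
        if i in stack:
            raise PedigreeError(f"pedigree cycle involving {i!r}")
        r = rows[i]
        if not r.father:
            depth[i] = 0
        else:
            depth[i] = 1 + max(visit(r.father, stack + (i,)), visit(r.mother, stack + (i,)))
        return depth[i]

    # iterative wrapper to keep recursion shallow on long chains
    for i in rows:
        visit(i, ())
    return depth


@dataclass(frozen=True)
class RelatednessMatrix:
    """Expected-genetic-covariance multipliers ``2Φ`` over phenotyped ids.

    ``values[i, j] = 2·φ(ids[i], ids[j])``; the diagonal is 1 for the
    non-inbred designs supported here.  ``families`` carries the family
    label of each id (the matrix is block diagonal by family).
    """

    ids: list[str]
    values: np.ndarray
    families: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("relatedness matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("relatedness matrix is not symmetric")

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(" ".join(self.ids) + "\n")
        np.savetxt(buf, self.values, fmt="%.10g")
        return buf.getvalue()


@dataclass(frozen=True)
class KinshipEigen:
    """Eigendecomposition of a relatedness matrix.

    ``rotation.T @ (2Φ) @ rotation == diag(eigenvalues)``; eigenvalues are
    sorted descending and clamped to be non-negative.  Rotating trait data
    by ``rotation.T`` turns correlated family observations into independent
    ones with variances ``σe² + λ·σg²``.
    """

    ids: list[str]
    eigenvalues: np.ndarray
    rotation: np.ndarray
    families: list[str] = field(default_factory=list)


def compute_relatedness(ped: Pedigree) -> RelatednessMatrix:
    """Build ``2Φ`` over the pedigree's phenotyped individuals.

    Kinship is computed by the generation recursion with memoisation; MZ
    co-twins are collapsed onto one genetic representative first, which
    makes them identical to each other and to third parties.
    """
    tab = ped.table
    rows = {r.id: r for r in tab.itertuples(index=False)}
    depth = _generation_depths(rows)

    # genetic representative: first listed member of each mz_group
    rep: dict[str, str] = {}
    for label, grp in tab[tab["mz_group"] != ""].groupby("mz_group", sort=False):
        members = list(grp["id"])
        for m in members:
            rep[m] = members[0]
    for i in rows:
        rep.setdefault(i, i)

    memo: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            r = rows[a]
            val = 0.5 if not r.father else 0.5 * (1.0 + phi(rep[r.father], rep[r.mother]))
        else:
            # recurse on the later-generation member; founders unrelated
            if depth[a] < depth[b]:
                a, b = b, a
            r = rows[a]
            val = 0.0 if not r.father else 0.5 * (phi(rep[r.father], b) + phi(rep[r.mother], b))
        memo[key] = val
        return val

    ids = ped.phenotyped_ids
    n = len(ids)
    out = np.empty((n, n))
    fam = dict(zip(tab["id"], tab["family"]))
    # cross-family entries are structurally zero; only fill within family
    out[:] = 0.0
    idx_by_fam: dict[str, list[int]] = {}
    for k, i in enumerate(ids):
        idx_by_fam.setdefault(fam[i], []).append(k)
    for members in idx_by_fam.values():
        for a in members:
            for b in members:
                if a == b:
                    out[a, a] = 2.0 * phi(rep[ids[a]], rep[ids[a]])
                elif rep[ids[a]] == rep[ids[b]]:
                    out[a, b] = 1.0  # MZ co-twins: genetically identical
                else:
                    out[a, b] = 2.0 * phi(rep[ids[a]], rep[ids[b]])
    return RelatednessMatrix(ids=ids, values=out, families=[fam[i] for i in ids])


def make_twin_pedigree(n_mz_pairs: int, n_dz_pairs: int,
                       phenotype_founders: bool = False) -> Pedigree:
    """Independent twin-pair families: two founder parents and two offspring
    per family, MZ pairs first.

    Total persons are ``4·(n_mz_pairs + n_dz_pairs)``.  With founders left
    unphenotyped, (125, 125) gives the canonical 1,000-person design with
    500 phenotyped twins.
    """
    if n_mz_pairs < 0 or n_dz_pairs < 0:
        raise ConfigurationError("pair counts must be non-negative")
    if n_mz_pairs + n_dz_pairs == 0:
        raise ConfigurationError("at least one twin pair is required")
    recs = []
    k = 0
    for kind, count in (("mz", n_mz_pairs), ("dz", n_dz_pairs)):
        for _ in range(count):
            famid = f"fam{k:04d}"
            fa, mo = f"{famid}-fa", f"{famid}-mo"
            t1, t2 = f"{famid}-t1", f"{famid}-t2"
            mz = f"{famid}-mz" if kind == "mz" else ""
            recs.append((fa, "", "", "male", "", famid, phenotype_founders))
            recs.append((mo, "", "", "female", "", famid, phenotype_founders))
            recs.append((t1, fa, mo, "male", mz, famid, True))
            recs.append((t2, fa, mo, "male" if kind == "mz" else "female", mz, famid, True))
            k += 1
    tab = pd.DataFrame(recs, columns=["id", "father", "mother", "sex",
                                      "mz_group", "family", "phenotyped"])
    return Pedigree(tab)


def eigendecompose(rel: RelatednessMatrix) -> KinshipEigen:
    """Eigendecompose ``2Φ`` family block by family block.

    Identical to a dense decomposition (the matrix is block diagonal by
    family) but scales linearly in family count.  Eigenvalues are pooled,
    clamped at zero, and sorted descending with their vectors.
    """
    v = rel.values
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValidationError("relatedness matrix is not symmetric")
    n = len(rel.ids)
    codes = pd.factorize(np.asarray(rel.families))[0]
    grouped = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    lam = np.empty(n)
    rot = np.zeros((n, n))
    # cache per distinct block content (all MZ blocks identical, etc.)
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for idx in np.split(grouped, np.cumsum(counts)[:-1]):
        block = v[np.ix_(idx, idx)]
        key = block.tobytes()
        if key not in cache:
            w, u = np.linalg.eigh(block)
            if w.min() < -_EIG_TOL:
                raise ValidationError(
                    f"relatedness block for family {rel.families[idx[0]]!r} is not PSD")
            cache[key] = (np.clip(w, 0.0, None), u)
        w, u = cache[key]
        lam[idx] = w
        rot[np.ix_(idx, idx)] = u
    order = np.argsort(-lam, kind="stable")
    return KinshipEigen(ids=list(rel.ids), eigenvalues=lam[order],
                        rotation=rot[:, order], families=list(rel.families))


# ---------------------------------------------------------------------------
# SOLAR-style CSV interface: id, fa, mo, sex, mztwin, famid

def read_pedigree_csv(path_or_buf, phenotyped=None) -> Pedigree:
    """Read a SOLAR-style pedigree CSV (``id,fa,mo,sex,mztwin,famid``).

    Empty ``fa``/``mo`` mark a founder, empty ``mztwin`` a non-twin.
    ``phenotyped`` is an id collection (default: everyone is phenotyped —
    phenotype files define the flag in practice).
    """
    raw = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    need = ["id", "fa", "mo", "sex", "mztwin", "famid"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise PedigreeError(f"pedigree CSV missing columns: {missing}")
    sex = raw["sex"].str.strip().str.lower().map(_SEX_CANON)
    if sex.isna().any():
        bad = raw.loc[sex.isna(), "sex"].iloc[0]
        raise PedigreeError(f"unrecognised sex code {bad!r}")
    tab = pd.DataFrame({
        "id": raw["id"].str.strip(),
        "father": raw["fa"].str.strip(),
        "mother": raw["mo"].str.strip(),
        "sex": sex,
        "mz_group": raw["mztwin"].str.strip(),
        "family": raw["famid"].str.strip(),
        "phenotyped": True,
    })
    ped = Pedigree(tab)
    if phenotyped is not None:
        ped = ped.with_phenotyped(phenotyped)
    return ped


def write_pedigree_csv(ped: Pedigree, path_or_buf) -> None:
    tab = ped.table
    out = pd.DataFrame({
        "id": tab["id"],
        "fa": tab["father"],
        "mo": tab["mother"],
        "sex": tab["sex"].map({"male": "m", "female": "f"}),
        "mztwin": tab["mz_group"],
        "famid": tab["family"],
    })
    out.to_csv(path_or_buf, index=False)
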