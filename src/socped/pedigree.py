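"""Pedigree data model, kinship and inbreeding coefficients.

The central objects of the package: a validated multigenerational
:class:`Pedigree` (a directed acyclic parent map with founders) together
with the classical identity-by-descent quantities computed from it —

* pairwise kinship ``k(i, j)`` (Malecot's coefficient de parente): the
  probability that homologous alleles sampled one from each individual
  are identical by descent;
* the inbreeding coefficient ``f_i = k(sire_i, dam_i)``: the probability
  that an individual's two homologous alleles are identical by descent;
* the additive (numerator) relationship matrix ``A`` with
  ``A[i, j] = 2 k(i, j)``, built by the tabular method, and its sparse
  inverse built directly from the pedigree (Henderson's rules with the
  Quaas adjustment for inbred parents);
* a Monte Carlo gene-drop estimator of kinship, used as an independent
  validation oracle for the exact recursions.

Founders (individuals with no recorded parents) are assumed mutually
unrelated and non-inbred.  When only one parent is recorded the unknown
side contributes zero kinship.
"""

from __future__ import annotations

import heapq
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "KinshipResult",
    "InbreedingResult",
    "GeneDropResult",
    "PedigreeValidationError",
    "RELATIONSHIP_LABELS",
    "read_pedigree",
    "write_pedigree",
]

#: tolerance below which a (dyadic-rational, exactly representable)
#: inbreeding or kinship value is treated as zero
F_EPS = 1e-12

RELATIONSHIP_LABELS = (
    "mother_son",
    "father_daughter",
    "full_sib",
    "paternal_half_sib",
    "maternal_half_sib",
    "grandmother_grandson",
    "grandfather_granddaughter",
    "other_related",
    "unrelated",
)


class PedigreeValidationError(ValueError):
    """Raised when a pedigree violates a structural invariant."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parent links, cohort and sex."""

    id: str
    sire: str | None = None
    dam: str | None = None
    cohort: int | None = None
    sex: str = "unknown"  # {male, female, unknown}


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[str, str]
    kinship: float


@dataclass(frozen=True)
class InbreedingResult:
    id: str
    f: float
    n_known_grandparents: int


@dataclass(frozen=True)
class GeneDropResult:
    pair: tuple[str, str]
    estimate: float
    se: float
    n_reps: int


class Pedigree:
    """A validated directed acyclic parent map.

    Parameters
    ----------
    records
        Iterable of :class:`PedigreeRecord`.  Parents named by a record
        but lacking a record of their own are auto-declared as founders
        of unknown cohort (their sex inferred from the slot they occupy).
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        records = list(records)
        seen: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.id in seen:
                raise PedigreeValidationError(f"duplicate id: {rec.id!r}")
            if rec.id == rec.sire or rec.id == rec.dam:
                raise PedigreeValidationError(f"self-parentage for id {rec.id!r}")
            seen[rec.id] = rec
        # auto-declare missing parents as founders
        for rec in list(seen.values()):
            for parent, psex in ((rec.sire, "male"), (rec.dam, "female")):
                if parent is not None and parent not in seen:
                    seen[parent] = PedigreeRecord(parent, sex=psex)
        self._records = seen
        self._check_sexes()
        self._order, self._rank = self._toposort()
        self._pos = {i: n for n, i in enumerate(self._order)}
        self._kin_cache: dict[tuple[str, str], float] = {}
        self._f_cache: dict[str, float] | None = None
        self._mendel_var: dict[str, float] | None = None

    # ---------------------------------------------------------------- basics

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, i: str) -> bool:
        return i in self._records

    def __getitem__(self, i: str) -> PedigreeRecord:
        try:
            return self._records[i]
        except KeyError:
            raise KeyError(f"unknown individual: {i!r}") from None

    @property
    def ids(self) -> list[str]:
        """Ids in topological order (parents before offspring)."""
        return list(self._order)

    def sire(self, i: str) -> str | None:
        return self[i].sire

    def dam(self, i: str) -> str | None:
        return self[i].dam

    def parents(self, i: str) -> tuple[str | None, str | None]:
        rec = self[i]
        return rec.sire, rec.dam

    def is_founder(self, i: str) -> bool:
        rec = self[i]
        return rec.sire is None and rec.dam is None

    @property
    def founders(self) -> list[str]:
        return [i for i in self._order if self.is_founder(i)]

    def depth(self) -> int:
        """Maximum generation rank (founders are rank 0)."""
        return max(self._rank.values()) if self._rank else 0

    def ancestors(self, *ids: str) -> set[str]:
        """Transitive ancestor closure including ``ids`` themselves."""
        todo = [self[i].id for i in ids]
        out: set[str] = set()
        while todo:
            i = todo.pop()
            if i in out:
                continue
            out.add(i)
            for p in self.parents(i):
                if p is not None:
                    todo.append(p)
        return out

    def _check_sexes(self) -> None:
        for rec in self._records.values():
            if rec.sire is not None and self._records[rec.sire].sex == "female":
                raise PedigreeValidationError(
                    f"sire {rec.sire!r} of {rec.id!r} is recorded as female"
                )
            if rec.dam is not None and self._records[rec.dam].sex == "male":
                raise PedigreeValidationError(
                    f"dam {rec.dam!r} of {rec.id!r} is recorded as male"
                )

    def _toposort(self) -> tuple[list[str], dict[str, int]]:
        """Kahn's algorithm parent->offspring; detects cycles.

        Rank = 1 + max(parent ranks); ties in the output order broken by
        id so downstream recursions are deterministic.
        """
        children: dict[str, list[str]] = {i: [] for i in self._records}
        indeg = {i: 0 for i in self._records}
        for rec in self._records.values():
            for p in (rec.sire, rec.dam):
                if p is not None:
                    children[p].append(rec.id)
                    indeg[rec.id] += 1
        heap = sorted(i for i, d in indeg.items() if d == 0)
        heapq.heapify(heap)
        rank = {i: 0 for i in heap}
        order: list[str] = []
        while heap:
            i = heapq.heappop(heap)
            order.append(i)
            for c in children[i]:
                rank[c] = max(rank.get(c, 0), rank[i] + 1)
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, c)
        if len(order) != len(self._records):
            stuck = sorted(set(self._records) - set(order))
            raise PedigreeValidationError(
                f"cycle in parent links involving: {', '.join(stuck[:5])}"
            )
        return order, rank

    # ------------------------------------------------------------- kinship

    def kinship(self, i: str, j: str) -> KinshipResult:
        """Exact kinship by the Malecot recursion.

        The individual of higher generation rank is decomposed onto its
        parents (it cannot be an ancestor of the other); self-kinship is
        ``(1 + f) / 2``; founders are mutually unrelated.
        """
        self[i], self[j]  # raise KeyError on unknown ids
        return KinshipResult((i, j), self._kin(i, j))

    def _kin(self, i: str | None, j: str | None) -> float:
        if i is None or j is None:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + self._f(i))
        key = (i, j) if i < j else (j, i)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        # decompose the deeper individual; at equal rank neither is an
        # ancestor of the other so either choice is valid
        if self._rank[i] > self._rank[j]:
            i, j = j, i
        sj, dj = self.parents(j)
        if sj is None and dj is None:
            val = 0.0
        else:
            val = 0.5 * (self._kin(i, sj) + self._kin(i, dj))
        self._kin_cache[key] = val
        return val

    def _f(self, i: str) -> float:
        s, d = self.parents(i)
        if s is None or d is None:
            return 0.0
        return self._kin(s, d)

    def inbreeding(self, i: str) -> InbreedingResult:
        """Inbreeding coefficient ``f_i`` = kinship of the parents.

        ``f`` is 0 by convention when either parent is unrecorded.
        """
        self[i]
        return InbreedingResult(i, self._f(i), self.known_grandparent_count(i))

    def inbreeding_all(self) -> dict[str, float]:
        """``f`` for every individual, by ancestor-weight accumulation.

        Uses the decomposition ``A = T D T'`` (T: expected genome
        contributions of ancestors, D: Mendelian sampling variances), so
        ``f_i = A[s_i, d_i] / 2 = sum_a t_{s,a} t_{d,a} d_a / 2``.  Runs
        in O(n * ancestors) and agrees with the pairwise recursion.
        """
        if self._f_cache is not None:
            return dict(self._f_cache)
        f: dict[str, float] = {}
        dvar: dict[str, float] = {}
        for i in self._order:
            s, d = self.parents(i)
            if s is None and d is None:
                f[i] = 0.0
                dvar[i] = 1.0
            elif s is None or d is None:
                p = s if s is not None else d
                f[i] = 0.0
                dvar[i] = 0.75 - 0.25 * f[p]
            else:
                ws = self._contributions(s)
                wd = self._contributions(d)
                if len(wd) < len(ws):
                    ws, wd = wd, ws
                a_sd = sum(w * wd.get(anc, 0.0) * dvar[anc] for anc, w in ws.items())
                f[i] = 0.5 * a_sd
                dvar[i] = 0.5 - 0.25 * (f[s] + f[d])
        self._f_cache = f
        self._mendel_var = dvar
        return dict(f)

    def _contributions(self, i: str) -> dict[str, float]:
        """Expected genome contribution of every ancestor to ``i``."""
        w = {i: 1.0}
        # reverse-topological sweep restricted to the ancestor closure
        for a in sorted(self.ancestors(i), key=self._pos.get, reverse=True):
            wa = w.get(a)
            if wa is None:
                continue
            for p in self.parents(a):
                if p is not None:
                    w[p] = w.get(p, 0.0) + 0.5 * wa
        return w

    def mendelian_variances(self) -> dict[str, float]:
        """Mendelian sampling variance d_i per individual (founders: 1)."""
        if self._mendel_var is None:
            self.inbreeding_all()
        return dict(self._mendel_var)

    # ------------------------------------------------- relationship matrix

    def relationship_matrix(self, ids: Sequence[str]) -> np.ndarray:
        """Additive relationship matrix A over ``ids`` (tabular method).

        ``A[i, j] = 2 k(i, j)``; computed over the full ancestor closure
        in topological order, then restricted to the requested ids.
        """
        for i in ids:
            self[i]
        closure = sorted(self.ancestors(*ids), key=self._pos.get)
        idx = {i: n for n, i in enumerate(closure)}
        m = len(closure)
        A = np.zeros((m, m))
        for i in closure:
            r = idx[i]
            s, d = self.parents(i)
            si = idx.get(s) if s is not None else None
            di = idx.get(d) if d is not None else None
            # off-diagonals with previously processed individuals
            for jname in closure[:r]:
                c = idx[jname]
                v = 0.0
                if si is not None:
                    v += 0.5 * A[c, si]
                if di is not None:
                    v += 0.5 * A[c, di]
                A[r, c] = A[c, r] = v
            A[r, r] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        sel = [idx[i] for i in ids]
        return A[np.ix_(sel, sel)]

    def a_inverse(self, ids: Sequence[str] | None = None):
        """Sparse inverse of A by Henderson's rules (Quaas adjustment).

        ``ids`` must be ancestrally closed (every recorded parent of a
        listed individual is listed); defaults to the whole pedigree.
        Returns ``(A_inv, order, logdet_A)`` where ``A_inv`` is CSC.
        """
        from scipy import sparse

        if ids is None:
            closure = list(self._order)
        else:
            closure = sorted(set(ids), key=self._pos.get)
            for i in closure:
                for p in self.parents(i):
                    if p is not None and p not in set(closure):
                        raise ValueError(
                            f"a_inverse requires an ancestrally closed id set; "
                            f"{p!r} (parent of {i!r}) is missing"
                        )
        idx = {i: n for n, i in enumerate(closure)}
        dvar = self.mendelian_variances()
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def add(r: int, c: int, v: float) -> None:
            rows.append(r)
            cols.append(c)
            vals.append(v)

        logdet = 0.0
        for i in closure:
            b = 1.0 / dvar[i]
            logdet += np.log(dvar[i])
            r = idx[i]
            ps = [idx[p] for p in self.parents(i) if p is not None]
            add(r, r, b)
            for p in ps:
                add(r, p, -0.5 * b)
                add(p, r, -0.5 * b)
            for p in ps:
                for q in ps:
                    add(p, q, 0.25 * b)
        m = len(closure)
        A_inv = sparse.csc_matrix(
            (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(m, m)
        )
        return A_inv, closure, logdet

    # ------------------------------------------------------------ gene drop

    def gene_drop_kinship(
        self, i: str, j: str, n_reps: int = 10_000, seed: int | None = None
    ) -> GeneDropResult:
        """Monte Carlo kinship by dropping founder-unique alleles.

        Each replicate assigns every founder (and every unrecorded
        parent slot) two globally unique alleles, transmits one allele
        per parent with probability 1/2 down the ancestor closure of the
        pair, then samples one allele from each of ``i`` and ``j``.  The
        estimate is the fraction of replicates in which the sampled
        alleles are identical by descent.
        """
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        self[i], self[j]
        rng = np.random.default_rng(seed)
        closure = sorted(self.ancestors(i, j), key=self._pos.get)
        alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        counter = 0
        for a in closure:
            pair = []
            for p in self.parents(a):
                if p is None:
                    pair.append(np.full(n_reps, counter, dtype=np.int64))
                    counter += 1
                else:
                    pa, pb = alleles[p]
                    pick = rng.integers(0, 2, n_reps).astype(bool)
                    pair.append(np.where(pick, pa, pb))
            if not pair:  # founder
                pair = [
                    np.full(n_reps, counter, dtype=np.int64),
                    np.full(n_reps, counter + 1, dtype=np.int64),
                ]
                counter += 2
            alleles[a] = (pair[0], pair[1])
        gi = np.where(rng.integers(0, 2, n_reps).astype(bool), *alleles[i])
        gj = np.where(rng.integers(0, 2, n_reps).astype(bool), *alleles[j])
        p_hat = float(np.mean(gi == gj))
        se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_reps))
        return GeneDropResult((i, j), p_hat, se, n_reps)

    # ----------------------------------------------- completeness / routes

    def known_grandparent_count(self, i: str) -> int:
        """Number of the four grandparent slots that are recorded.

        A slot counts only when the intermediate parent is itself
        recorded and that parent's relevant parent is recorded.
        """
        n = 0
        for p in self.parents(i):
            if p is None:
                continue
            for gp in self.parents(p):
                if gp is not None:
                    n += 1
        return n

    def restrict(self, min_grandparents: int = 1) -> set[str]:
        """Ids with both parents known and >= ``min_grandparents`` known.

        Mirrors the completeness restriction used when estimating
        population inbreeding rates: individuals with shallow pedigrees
        are excluded because their f would be biased toward zero.
        """
        if not 0 <= min_grandparents <= 4:
            raise ValueError("min_grandparents must be in 0..4")
        out = set()
        for i in self._order:
            s, d = self.parents(i)
            if s is None or d is None:
                continue
            if self.known_grandparent_count(i) >= min_grandparents:
                out.add(i)
        return out

    def classify_relationship(self, male: str, female: str) -> str:
        """Closest-path relationship label for a (male, female) pair.

        Inspects shared ancestry up to two generations; related pairs
        not matching a named route are ``other_related``; kinship-zero
        pairs are ``unrelated``.
        """
        mrec, frec = self[male], self[female]
        if mrec.dam == female:
            return "mother_son"
        if frec.sire == male:
            return "father_daughter"
        ms, md = mrec.sire, mrec.dam
        fs, fd = frec.sire, frec.dam
        if ms is not None and ms == fs and md is not None and md == fd:
            return "full_sib"
        if ms is not None and ms == fs:
            return "paternal_half_sib"
        if md is not None and md == fd:
            return "maternal_half_sib"
        male_grandmothers = {self.dam(p) for p in (ms, md) if p is not None}
        if female in male_grandmothers:
            return "grandmother_grandson"
        female_grandfathers = {self.sire(p) for p in (fs, fd) if p is not None}
        if male in female_grandfathers:
            return "grandfather_granddaughter"
        if self._kin(male, female) > F_EPS:
            return "other_related"
        return "unrelated"

    # ---------------------------------------------------------- conversion

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.id,
                "sire": r.sire,
                "dam": r.dam,
                "cohort": r.cohort,
                "sex": r.sex,
            }
            for r in (self._records[i] for i in self._order)
        ]
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort", "sex"])


# ------------------------------------------------------------------- file IO

_SEX_TO_LINKAGE = {"male": "1", "female": "2", "unknown": "0"}
_LINKAGE_TO_SEX = {v: k for k, v in _SEX_TO_LINKAGE.items()}


def read_pedigree(path, dialect: str = "csv") -> Pedigree:
    """Read a pedigree from ``csv`` or ``linkage`` format.

    CSV: header ``id,sire,dam,cohort,sex``, empty field = missing.
    LINKAGE: whitespace-delimited ``family id sire dam sex`` with 0 for
    missing parents and sex coded 1=male, 2=female, 0=unknown.
    """
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"id", "sire", "dam"}
        if not required.issubset(df.columns):
            raise PedigreeValidationError(
                f"pedigree CSV must have columns {sorted(required)}; got {list(df.columns)}"
            )
        records = []
        for row in df.itertuples(index=False):
            cohort = getattr(row, "cohort", "")
            records.append(
                PedigreeRecord(
                    id=row.id,
                    sire=row.sire or None,
                    dam=row.dam or None,
                    cohort=int(float(cohort)) if cohort not in ("", None) else None,
                    sex=getattr(row, "sex", "") or "unknown",
                )
            )
        return Pedigree(records)
    if dialect == "linkage":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["family", "id", "sire", "dam", "sex"],
            dtype=str,
        )
        records = [
            PedigreeRecord(
                id=row.id,
                sire=None if row.sire == "0" else row.sire,
                dam=None if row.dam == "0" else row.dam,
                sex=_LINKAGE_TO_SEX.get(row.sex, "unknown"),
            )
            for row in df.itertuples(index=False)
        ]
        return Pedigree(records)
    raise ValueError(f"unknown pedigree dialect: {dialect!r}")


def write_pedigree(ped: Pedigree, path, dialect: str = "csv") -> None:
    """Write a pedigree in ``csv`` or ``linkage`` format (see reader)."""
    df = ped.to_frame()
    if dialect == "csv":
        out = df.copy()
        out["cohort"] = out["cohort"].map(
            lambda c: "" if c is None or pd.isna(c) else str(int(c))
        )
        for col in ("sire", "dam"):
            out[col] = out[col].fillna("")
        out.to_csv(path, index=False)
        return
    if dialect == "linkage":
        with open(path, "w") as fh:
            for r in df.itertuples(index=False):
                fh.write(
                    f"1 {r.id} {r.sire or 0} {r.dam or 0} "
                    f"{_SEX_TO_LINKAGE.get(r.sex, '0')}\n"
                )
        return
    raise ValueError(f"unknown pedigree dialect: {dialect!r}")
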