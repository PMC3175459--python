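"""Pedigree-expected additive relationships and Mendelian-consistency checks."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypeTable, Pedigree, RelationshipMatrix, MISSING_ALLELE


def additive_matrix(pedigree: Pedigree, subjects: Sequence[str] | None = None) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method, with inbreeding.

    Built over the full pedigree in topological order (so inbreeding through
    non-phenotyped ancestors is counted), then subset to ``subjects``.
    Diagonal is 1 + F; parent-offspring entries are 0.5 for non-inbred
    parents.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        # relationship to all earlier individuals
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    mat = RelationshipMatrix(tuple(pedigree.ids), A, role="pedigree-additive")
    if subjects is not None:
        mat = mat.subset(list(subjects))
    return mat


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Per-individual inbreeding coefficients F (A diagonal minus one)."""
    return np.diag(additive_matrix(pedigree).values) - 1.0


@dataclass(frozen=True)
class MendelViolation:
    marker: str
    individual: str
    kind: str  # trio-inconsistent | sibship-inconsistent
    description: str


def _trio_compatible(child, sire, dam) -> bool:
    """Child shares >=1 allele with each typed parent; the two shared alleles
    can be drawn from distinct parents."""
    c1, c2 = child
    for a, b in ((c1, c2), (c2, c1)):
        ok_s = sire is None or a in sire
        ok_d = dam is None or b in dam
        if ok_s and ok_d:
            return True
    return False


def mendel_check(pedigree: Pedigree, genotypes: GenotypeTable, marker: str) -> list[MendelViolation]:
    """Trio checks followed by Lange-Goradia genotype elimination.

    Returns one violation per genotyped individual whose genotype is either
    directly incompatible with a typed parent (``trio-inconsistent``) or
    whose genotype set empties during elimination across the pedigree
    (``sibship-inconsistent``).  A dummy allele label stands in for alleles
    not observed at the marker, so untyped ancestors never trigger false
    positives.
    """
    obs = {}
    for iid in genotypes.ids:
        a, b = genotypes.get(iid, marker)
        if a != MISSING_ALLELE and b != MISSING_ALLELE:
            obs[iid] = (min(a, b), max(a, b))
    alleles = genotypes.alleles(marker)
    dummy = (max(alleles) if alleles else 0) + 1
    universe = alleles + [dummy]

    violations: list[MendelViolation] = []
    flagged: set[str] = set()

    # direct trio screen
    for i, iid in enumerate(pedigree.ids):
        if iid not in obs:
            continue
        si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
        gs = obs.get(pedigree.ids[si]) if si >= 0 else None
        gd = obs.get(pedigree.ids[di]) if di >= 0 else None
        if (gs is not None or gd is not None) and not _trio_compatible(obs[iid], gs, gd):
            violations.append(
                MendelViolation(
                    marker,
                    iid,
                    "trio-inconsistent",
                    f"child {obs[iid]} incompatible with sire {gs} / dam {gd}",
                )
            )
            flagged.add(iid)

    # genotype elimination to fixpoint; trio-flagged genotypes are treated
    # as untyped so one bad trio does not cascade through the family
    all_pairs = frozenset(combinations_with_replacement(universe, 2))
    children_of: dict[tuple[int, int], list[int]] = {}
    for i in range(pedigree.n):
        si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if si >= 0 and di >= 0:
            children_of.setdefault((si, di), []).append(i)

    def offspring_ok(gc, gs, gd) -> bool:
        return (gc[0] in gs and gc[1] in gd) or (gc[1] in gs and gc[0] in gd)

    def eliminate(masked: set[str]) -> set[str]:
        """Run elimination with ``masked`` ids untyped; return emptied typed ids."""
        gsets: list[set] = []
        for iid in pedigree.ids:
            if iid in obs and iid not in flagged and iid not in masked:
                gsets.append({obs[iid]})
            else:
                gsets.append(set(all_pairs))
        changed = True
        while changed:
            changed = False
            for (si, di), kids in children_of.items():
                # joint parental screen: a (sire, dam) genotype pair survives
                # only if every child has a compatible genotype
                keep_s, keep_d = set(), set()
                keep_k = {k: set() for k in kids}
                for gs in gsets[si]:
                    for gd in gsets[di]:
                        per_kid = []
                        ok = True
                        for k in kids:
                            comp = [gc for gc in gsets[k] if offspring_ok(gc, gs, gd)]
                            if not comp and gsets[k]:
                                ok = False
                                break
                            per_kid.append((k, comp))
                        if ok:
                            keep_s.add(gs)
                            keep_d.add(gd)
                            for k, comp in per_kid:
                                keep_k[k].update(comp)
                for idx, keep in ((si, keep_s), (di, keep_d)):
                    if keep != gsets[idx]:
                        gsets[idx].intersection_update(keep)
                        changed = True
                for k in kids:
                    if keep_k[k] != gsets[k]:
                        gsets[k].intersection_update(keep_k[k])
                        changed = True
        return {
            iid
            for i, iid in enumerate(pedigree.ids)
            if iid in obs and iid not in flagged and iid not in masked and not gsets[i]
        }

    emptied = eliminate(set())
    if emptied:
        # attribute minimally: an individual is a culprit if masking its
        # genotype alone restores consistency; fall back to the whole set
        culprits = {iid for iid in emptied if not eliminate({iid})}
        for iid in sorted(culprits or emptied):
            violations.append(
                MendelViolation(
                    marker,
                    iid,
                    "sibship-inconsistent",
                    f"genotype {obs[iid]} eliminated by pedigree-wide constraint propagation",
                )
            )
    return violations


def blank_violations(
    genotypes: GenotypeTable, violations: Sequence[MendelViolation]
) -> GenotypeTable:
    """Copy of the genotype table with each violating genotype set missing.

    Only the offending (marker, individual) entries are blanked; individuals
    are never dropped."""
    data = genotypes.data.copy()
    id_index = {i: k for k, i in enumerate(genotypes.ids)}
    m_index = {m: k for k, m in enumerate(genotypes.markers)}
    for viol in violations:
        i = id_index.get(viol.individual)
        j = m_index.get(viol.marker)
        if i is not None and j is not None:
            data[i, j] = MISSING_ALLELE
    return GenotypeTable(genotypes.ids, genotypes.markers, data)


def violations_to_frame(violations: Sequence[MendelViolation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.marker, v.individual, v.kind, v.description) for v in violations],
        columns=["marker", "id", "kind", "description"],
    )
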