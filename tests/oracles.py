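"""Independent reference implementations used only by the tests.

These deliberately avoid the package's algorithms: kinship comes from an
exact enumeration of meiosis outcomes (gene dropping over every possible
inheritance-bit assignment), not the kinship recursion.
"""

from __future__ import annotations

import itertools

import numpy as np


def kinship_enumeration(ped) -> tuple[list[str], np.ndarray]:
    """Exact 2*phi over phenotyped individuals by enumerating all meiosis
    outcomes.

    Every non-founder 'genome' (MZ co-twins share one) carries two
    inheritance bits choosing which paternal/maternal allele was
    transmitted.  Enumerating all bit assignments per family and averaging
    allele identity over the four allele pairings gives kinship exactly.
    Feasible for the small families the builders produce.
    """
    tab = ped.table
    rows = {r.id: r for r in tab.itertuples(index=False)}
    rep = {}
    for label, grp in tab[tab["mz_group"] != ""].groupby("mz_group", sort=False):
        members = list(grp["id"])
        for m in members:
            rep[m] = members[0]
    for i in rows:
        rep.setdefault(i, i)

    ids = ped.phenotyped_ids
    fam_of = dict(zip(tab["id"], tab["family"]))
    n = len(ids)
    out = np.zeros((n, n))
    for f in tab["family"].unique():
        members = [i for i in tab["id"] if fam_of[i] == f]
        pheno_idx = [(k, i) for k, i in enumerate(ids) if fam_of[i] == f]
        if not pheno_idx:
            continue
        genomes = sorted({rep[i] for i in members if rows[i].father})
        founders = [i for i in members if not rows[i].father]
        # topological order within the family for allele resolution
        order, resolved = [], set(founders)
        pending = list(genomes)
        while pending:
            progressed = False
            for g in list(pending):
                r = rows[g]
                if rep[r.father] in resolved and rep[r.mother] in resolved:
                    order.append(g)
                    resolved.add(g)
                    pending.remove(g)
                    progressed = True
            assert progressed, "cyclic family"
        acc = np.zeros((len(pheno_idx), len(pheno_idx)))
        count = 0
        for bits in itertools.product((0, 1), repeat=2 * len(order)):
            alleles = {i: ((i, 0), (i, 1)) for i in founders}
            for k, g in enumerate(order):
                r = rows[g]
                pa = alleles[rep[r.father]][bits[2 * k]]
                ma = alleles[rep[r.mother]][bits[2 * k + 1]]
                alleles[g] = (pa, ma)
            for i in members:
                alleles.setdefault(i, alleles[rep[i]])
            for a, (_, ia) in enumerate(pheno_idx):
                for b, (_, ib) in enumerate(pheno_idx):
                    same = sum(x == y for x in alleles[ia] for y in alleles[ib])
                    acc[a, b] += same / 4.0
            count += 1
        acc /= count
        for a, (ka, _) in enumerate(pheno_idx):
            for b, (kb, _) in enumerate(pheno_idx):
                out[ka, kb] = 2.0 * acc[a, b]
    return ids, out
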