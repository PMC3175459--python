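"""Independent oracles for the test suite.

These re-derive expected values by brute force or closed form, sharing no
estimation code with the package: a transfer-matrix exhaustive enumeration
of descent states for IBD, a gene-dropping kinship estimator for the
A-matrix, and direct REML likelihood evaluation for the mixed-model fits.
"""

import itertools

import numpy as np


def haldane_r(d_cm):
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def slot_of(ped, S_loc):
    """Founder-slot pair per individual, derived directly from the pedigree
    arrays (no package kernel)."""
    fp = np.zeros(ped.n, dtype=int)
    fm = np.zeros(ped.n, dtype=int)
    for i in range(ped.n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0:
            fp[i] = 2 * ped.founder_ord[i]
            fm[i] = 2 * ped.founder_ord[i] + 1
        else:
            k = ped.nonfounder_ord[i]
            fp[i] = fp[si] if S_loc[2 * k] == 0 else fm[si]
            fm[i] = fp[di] if S_loc[2 * k + 1] == 0 else fm[di]
    return fp, fm


def ibd_matrix_of_config(ped, S_loc):
    fp, fm = slot_of(ped, S_loc)
    n = ped.n
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                M[i, j] = 1.0 + (1.0 if fp[i] == fm[i] else 0.0)
            else:
                M[i, j] = 0.5 * sum(
                    1 for a in (fp[i], fm[i]) for b in (fp[j], fm[j]) if a == b
                )
    return M


def phase_consistent(ped, S_loc, genotypes_at_locus, founder_genotypes):
    """Existence check by brute force over founder phase assignments.

    Requires every founder genotyped; genotypes_at_locus maps individual
    index -> (a, b)."""
    fp, fm = slot_of(ped, S_loc)
    founders = [i for i in range(ped.n) if ped.is_founder[i]]
    for phases in itertools.product([0, 1], repeat=len(founders)):
        sa = {}
        for k, i in enumerate(founders):
            a, b = founder_genotypes[i]
            if phases[k]:
                a, b = b, a
            f = ped.founder_ord[i]
            sa[2 * f], sa[2 * f + 1] = a, b
        ok = True
        for i, (a, b) in genotypes_at_locus.items():
            if {int(sa[fp[i]]), int(sa[fm[i]])} != {int(a), int(b)}:
                ok = False
                break
        if ok:
            return True
    return False


def exact_ibd_by_enumeration(ped, positions, genotypes):
    """Exact posterior-mean IBD matrices at every locus.

    Exhaustive over all 2^(n_meioses * n_loci) descent states, organised as
    a transfer matrix over the 2^n_meioses per-locus configurations: the
    target law is the Haldane Markov prior restricted to genotype-consistent
    states, identical in substance to summing over every state.  ``genotypes``
    is an (n, L, 2) array with every founder genotyped."""
    n_mei = ped.n_meioses
    L = len(positions)
    nc = 2**n_mei
    configs = np.array(
        [[(c >> m) & 1 for m in range(n_mei)] for c in range(nc)], dtype=np.uint8
    )
    founder_genotypes = {
        i: (genotypes[i, 0, 0], genotypes[i, 0, 1]) for i in range(ped.n) if ped.is_founder[i]
    }
    cons = np.zeros((L, nc), dtype=bool)
    for l in range(L):
        fg = {i: tuple(genotypes[i, l]) for i in range(ped.n) if ped.is_founder[i]}
        obs = {
            i: tuple(genotypes[i, l])
            for i in range(ped.n)
            if genotypes[i, l, 0] != 0 and genotypes[i, l, 1] != 0
        }
        for c in range(nc):
            cons[l, c] = phase_consistent(ped, configs[c], obs, fg)
    ham = np.zeros((nc, nc), dtype=np.int64)
    for c in range(nc):
        ham[c] = [bin(c ^ c2).count("1") for c2 in range(nc)]
    r = haldane_r(np.diff(np.asarray(positions, dtype=float)))
    T = [(r[l] ** ham) * ((1 - r[l]) ** (n_mei - ham)) for l in range(L - 1)]
    F = [np.where(cons[0], 1.0, 0.0)]
    for l in range(1, L):
        F.append((F[-1] @ T[l - 1]) * cons[l])
    B = [None] * L
    B[L - 1] = np.ones(nc)
    for l in range(L - 2, -1, -1):
        B[l] = T[l] @ (B[l + 1] * cons[l + 1])
    out = []
    for l in range(L):
        post = F[l] * B[l]
        if post.sum() <= 0:
            raise ValueError("no consistent descent state at locus %d" % l)
        post /= post.sum()
        M = np.zeros((ped.n, ped.n))
        for c in np.nonzero(post > 0)[0]:
            M += post[c] * ibd_matrix_of_config(ped, configs[c])
        out.append(M)
    return out


def gene_drop_kinship(ped, n_reps, seed=0):
    """Twice-kinship matrix estimated by dropping one unlinked locus
    ``n_reps`` times and scoring allele sharing of random gamete picks.

    Founder gametes carry unique labels; entry(i,j) estimates
    E[0.5 * sum of IBD indicators over the 4 gamete pairs], i.e. the
    additive relationship; diagonal 1 + inbreeding."""
    rng = np.random.default_rng(seed)
    n = ped.n
    lab_p = np.zeros((n_reps, n), dtype=np.int32)
    lab_m = np.zeros((n_reps, n), dtype=np.int32)
    for i in range(n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0:
            lab_p[:, i] = 2 * ped.founder_ord[i]
            lab_m[:, i] = 2 * ped.founder_ord[i] + 1
        else:
            pick = rng.integers(0, 2, size=n_reps)
            lab_p[:, i] = np.where(pick == 0, lab_p[:, si], lab_m[:, si])
            pick = rng.integers(0, 2, size=n_reps)
            lab_m[:, i] = np.where(pick == 0, lab_p[:, di], lab_m[:, di])
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            share = (
                (lab_p[:, i] == lab_p[:, j]).astype(float)
                + (lab_p[:, i] == lab_m[:, j])
                + (lab_m[:, i] == lab_p[:, j])
                + (lab_m[:, i] == lab_m[:, j])
            )
            if i == j:
                A[i, i] = 1.0 + np.mean(lab_p[:, i] == lab_m[:, i])
            else:
                A[i, j] = A[j, i] = 0.5 * np.mean(share)
    return A


def reml_loglik_direct(y, X, V):
    """Standard REML log-likelihood evaluated directly (no projection)."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + float(r @ Vi @ r)
    )
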