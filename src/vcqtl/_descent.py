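"""Numba kernels for descent-graph sampling.

A descent state assigns every non-founder meiosis a segregation indicator
(0 = grandpaternal, 1 = grandmaternal) at every locus of one linkage group.
Founder gametes occupy "slots" 2f and 2f+1; propagating indicators down the
pedigree maps every individual's two gametes to founder slots.  A state is
consistent with the observed genotypes at a locus iff some assignment of
alleles to founder slots reproduces every observed genotype (the classic
founder-allele-graph check).

Meiosis convention: non-founder ordinal k owns meiosis 2k (paternal gamete)
and 2k+1 (maternal gamete); indicator 0 picks the parent's paternal slot.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def slots_at(sire, dam, founder_ord, nonf_ord, s_loc, fp, fm):
    """Fill founder-slot ids fp/fm for every individual (topological order)."""
    n = sire.shape[0]
    for i in range(n):
        if sire[i] < 0:
            fp[i] = 2 * founder_ord[i]
            fm[i] = 2 * founder_ord[i] + 1
        else:
            k = nonf_ord[i]
            si = sire[i]
            di = dam[i]
            fp[i] = fp[si] if s_loc[2 * k] == 0 else fm[si]
            fm[i] = fp[di] if s_loc[2 * k + 1] == 0 else fm[di]


@njit(cache=True)
def _propagate(forced, head, nxt, eind, eu, ev, ea, eb, stack, trail, t0, seed):
    """Force alleles outward from ``seed``; record newly forced slots in trail[t0:].

    Returns (ok, new_trail_length)."""
    top = 0
    stack[top] = seed
    top += 1
    tlen = t0
    while top > 0:
        top -= 1
        u = stack[top]
        x = forced[u]
        p = head[u]
        while p >= 0:
            e = eind[p]
            v = ev[e] if eu[e] == u else eu[e]
            if x == ea[e]:
                need = eb[e]
            elif x == eb[e]:
                need = ea[e]
            else:
                return False, tlen
            if forced[v] == 0:
                forced[v] = need
                trail[tlen] = v
                tlen += 1
                stack[top] = v
                top += 1
            elif forced[v] != need:
                return False, tlen
            p = nxt[p]
    return True, tlen


@njit(cache=True)
def locus_consistent(
    sire, dam, founder_ord, nonf_ord, s_loc, a1, a2, active, n_slots,
    fp, fm, forced, eu, ev, ea, eb, head, nxt, eind, stack, trail,
):
    """True iff some founder-allele assignment reproduces all active genotypes."""
    n = sire.shape[0]
    slots_at(sire, dam, founder_ord, nonf_ord, s_loc, fp, fm)
    for s in range(n_slots):
        forced[s] = 0
        head[s] = -1
    ne = 0
    for i in range(n):
        if not active[i]:
            continue
        a = a1[i]
        b = a2[i]
        if a == 0 or b == 0:
            continue
        u = fp[i]
        v = fm[i]
        if u == v:
            if a != b:
                return False
            if forced[u] != 0 and forced[u] != a:
                return False
            forced[u] = a
        elif a == b:
            if forced[u] != 0 and forced[u] != a:
                return False
            forced[u] = a
            if forced[v] != 0 and forced[v] != a:
                return False
            forced[v] = a
        else:
            eu[ne] = u
            ev[ne] = v
            ea[ne] = a
            eb[ne] = b
            ne += 1
    for e in range(ne):
        nxt[2 * e] = head[eu[e]]
        eind[2 * e] = e
        head[eu[e]] = 2 * e
        nxt[2 * e + 1] = head[ev[e]]
        eind[2 * e + 1] = e
        head[ev[e]] = 2 * e + 1
    # propagate implications of directly forced slots
    for s in range(n_slots):
        if forced[s] != 0 and head[s] >= 0:
            ok, _ = _propagate(forced, head, nxt, eind, eu, ev, ea, eb, stack, trail, 0, s)
            if not ok:
                return False
    # components with no forced slot: each heterozygous edge allows two
    # assignments of its endpoints; try both
    for e in range(ne):
        if forced[eu[e]] == 0:
            seed = eu[e]
            forced[seed] = ea[e]
            trail[0] = seed
            ok, tl = _propagate(forced, head, nxt, eind, eu, ev, ea, eb, stack, trail, 1, seed)
            if not ok:
                for t in range(tl):
                    forced[trail[t]] = 0
                forced[seed] = eb[e]
                trail[0] = seed
                ok, tl = _propagate(forced, head, nxt, eind, eu, ev, ea, eb, stack, trail, 1, seed)
                if not ok:
                    return False
    return True


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (Python-level np.random.seed does not)."""
    np.random.seed(seed)


@njit(cache=True)
def init_locus(
    sire, dam, founder_ord, nonf_ord, s_loc, a1, a2, max_restarts, n_slots,
    active, fp, fm, forced, eu, ev, ea, eb, head, nxt, eind, stack, trail,
):
    """Greedy consistency-respecting assignment of one locus' indicators.

    Sequential imputation in topological order with random tie-breaking and
    full restarts on dead ends.  Returns True on success (s_loc filled)."""
    n = sire.shape[0]
    for _attempt in range(max_restarts):
        for i in range(n):
            active[i] = False
        ok = True
        for i in range(n):
            active[i] = True
            if sire[i] < 0:
                continue
            k = nonf_ord[i]
            start = np.random.randint(4)
            placed = False
            for t in range(4):
                c = (start + t) & 3
                s_loc[2 * k] = c & 1
                s_loc[2 * k + 1] = (c >> 1) & 1
                if locus_consistent(
                    sire, dam, founder_ord, nonf_ord, s_loc, a1, a2, active, n_slots,
                    fp, fm, forced, eu, ev, ea, eb, head, nxt, eind, stack, trail,
                ):
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return True
    return False


@njit(cache=True)
def mcmc_run(
    sire, dam, founder_ord, nonf_ord, a1, a2,  # a1/a2: (n, L) alleles, 0 missing
    log_r, log_1mr,  # (L-1,) Haldane switch log-probabilities
    S,  # (L, n_mei) uint8 state, modified in place
    n_iter, burn_in, thin, p_segment, seed, n_slots,
    out,  # (n_samples, L, n_mei) uint8
    active, fp, fm, forced, eu, ev, ea, eb, head, nxt, eind, stack, trail,
):
    """Metropolis sampler over descent states, prior x 0/1 consistency target.

    One iteration sweeps all meioses; each meiosis proposes either a single
    random-locus indicator flip or a tail segment flip (all loci from a
    random start onward, which crosses exactly one inter-locus transition).
    Returns (n_stored, n_proposed, n_accepted)."""
    np.random.seed(seed)
    L = S.shape[0]
    n_mei = S.shape[1]
    n = sire.shape[0]
    for i in range(n):
        active[i] = True
    ns = 0
    proposed = 0
    accepted = 0
    for it in range(n_iter):
        for m in range(n_mei):
            proposed += 1
            if L > 1 and np.random.random() < p_segment:
                l0 = np.random.randint(L)
                # prior ratio: only the (l0-1 -> l0) transition changes
                if l0 > 0:
                    same = S[l0 - 1, m] == S[l0, m]
                    dlp = (log_r[l0 - 1] - log_1mr[l0 - 1]) if same else (log_1mr[l0 - 1] - log_r[l0 - 1])
                else:
                    dlp = 0.0
                # Barker acceptance keeps the chain aperiodic even when the
                # prior ratio is 1 (e.g. uninformative single-locus groups)
                if np.random.random() >= 1.0 / (1.0 + np.exp(-dlp)):
                    continue
                for l in range(l0, L):
                    S[l, m] = 1 - S[l, m]
                ok = True
                for l in range(l0, L):
                    if not locus_consistent(
                        sire, dam, founder_ord, nonf_ord, S[l], a1[:, l], a2[:, l], active, n_slots,
                        fp, fm, forced, eu, ev, ea, eb, head, nxt, eind, stack, trail,
                    ):
                        ok = False
                        break
                if ok:
                    accepted += 1
                else:
                    for l in range(l0, L):
                        S[l, m] = 1 - S[l, m]
            else:
                l = np.random.randint(L)
                cur = S[l, m]
                dlp = 0.0
                if l > 0:
                    same = S[l - 1, m] == cur
                    dlp += (log_r[l - 1] - log_1mr[l - 1]) if same else (log_1mr[l - 1] - log_r[l - 1])
                if l < L - 1:
                    same = S[l + 1, m] == cur
                    dlp += (log_r[l] - log_1mr[l]) if same else (log_1mr[l] - log_r[l])
                if np.random.random() >= 1.0 / (1.0 + np.exp(-dlp)):
                    continue
                S[l, m] = 1 - cur
                if locus_consistent(
                    sire, dam, founder_ord, nonf_ord, S[l], a1[:, l], a2[:, l], active, n_slots,
                    fp, fm, forced, eu, ev, ea, eb, head, nxt, eind, stack, trail,
                ):
                    accepted += 1
                else:
                    S[l, m] = cur
        if it >= burn_in and (it - burn_in) % thin == 0 and ns < out.shape[0]:
            for l in range(L):
                for m in range(n_mei):
                    out[ns, l, m] = S[l, m]
            ns += 1
    return ns, proposed, accepted


@njit(cache=True)
def bridge_indicators(S_samples, lidx, ridx, p_keep_same, p_keep_left, seed, out):
    """Draw per-sample indicators at an off-marker position.

    ``lidx``/``ridx`` are flanking marker indices (either may be -1 beyond a
    chromosome end).  ``p_keep_same`` = P(indicator equals the flanking value
    | both flanks equal); ``p_keep_left`` = P(equals left | flanks differ).
    Fills out (n_samples, n_mei)."""
    np.random.seed(seed)
    n_samples = S_samples.shape[0]
    n_mei = S_samples.shape[2]
    for s in range(n_samples):
        for m in range(n_mei):
            if lidx < 0:
                sr = S_samples[s, ridx, m]
                out[s, m] = sr if np.random.random() < p_keep_same else 1 - sr
            elif ridx < 0:
                sl = S_samples[s, lidx, m]
                out[s, m] = sl if np.random.random() < p_keep_same else 1 - sl
            else:
                sl = S_samples[s, lidx, m]
                sr = S_samples[s, ridx, m]
                if sl == sr:
                    out[s, m] = sl if np.random.random() < p_keep_same else 1 - sl
                else:
                    out[s, m] = sl if np.random.random() < p_keep_left else sr


@njit(cache=True)
def fill_slot_counts(sire, dam, founder_ord, nonf_ord, indicators, subj_idx, fp, fm, C, n_slots):
    """Scatter per-sample founder-slot counts of the subjects into C.

    ``indicators``: (n_samples_block, n_mei); C: (n_subj, n_slots*block);
    column block s occupies C[:, s*n_slots : (s+1)*n_slots]."""
    nb = indicators.shape[0]
    for s in range(nb):
        slots_at(sire, dam, founder_ord, nonf_ord, indicators[s], fp, fm)
        base = s * n_slots
        for j in range(subj_idx.shape[0]):
            i = subj_idx[j]
            C[j, base + fp[i]] += 1.0
            C[j, base + fm[i]] += 1.0
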