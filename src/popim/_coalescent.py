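"""Structured-coalescent event engine for the nested three-population model.

Time runs backwards in units of 2*N_ref generations.  The model is
(WN, (EA, EB)): three extant demes WN, EA, EB until the EA/EB merger at
``T2``, then WN and the merged Eastern deme E until the root merger at
``T1``, then a single ancestral deme of relative size 1.  Within a deme of
relative size nu, each lineage pair coalesces at rate 1/nu; a lineage in
deme a migrates to deme b at rate M_ab/2 (so M is on the 4*N_ref*m scale).

Two engines share this event logic:

* :func:`simulate_genealogy` — pure Python, returns every branch with its
  descendant-leaf set; used to drop infinite-sites mutations onto
  haplotypes (run once per dataset).
* :func:`accumulate_branch_lengths` — JIT-compiled inner loop that only
  tracks per-population descendant counts and accumulates branch length
  into joint-SFS cells; used thousands of times per likelihood surface.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# deme codes used throughout: 0 = WN, 1 = EA (then E after T2), 2 = EB


def simulate_genealogy(rng, n_chrom, params):
    """Simulate one genealogy; return a list of (leaf_indices, length) branches.

    ``n_chrom`` is a (WN, EA, EB) tuple of chromosome counts.  Leaves are
    numbered 0..sum(n_chrom)-1 in population-block order.  The root lineage
    carries no branch.
    """
    n1, n2, n3 = n_chrom
    demes = [0] * n1 + [1] * n2 + [2] * n3
    births = [0.0] * (n1 + n2 + n3)
    leaves = [[i] for i in range(n1 + n2 + n3)]
    branches = []
    t = 0.0
    phase = 0  # 0: three demes, 1: WN+E, 2: ancestral
    T1, T2 = params.T1, params.T2

    while len(demes) > 1:
        if phase == 0 and t >= T2:
            demes = [0 if d == 0 else 1 for d in demes]
            phase = 1
        if phase <= 1 and t >= T1:
            demes = [0] * len(demes)
            phase = 2

        if phase == 0:
            sizes = {0: params.nu_WN, 1: params.nu_EA, 2: params.nu_EB}
            mig = [(0, 1, params.M_WN_EA), (0, 2, params.M_WN_EB),
                   (1, 2, params.M_EA_EB)]
            t_end = T2
        elif phase == 1:
            sizes = {0: params.nu_WN, 1: params.nu_E}
            mig = [(0, 1, params.M_WN_E)]
            t_end = T1
        else:
            sizes = {0: 1.0}
            mig = []
            t_end = math.inf

        counts = {d: 0 for d in sizes}
        for d in demes:
            counts[d] += 1

        rates = []  # (kind, payload, rate)
        for d, nu in sizes.items():
            k = counts[d]
            if k >= 2:
                rates.append(("coal", d, k * (k - 1) / 2.0 / nu))
        for a, b, M in mig:
            if M > 0:
                rates.append(("mig", (a, b), M / 2.0 * (counts[a] + counts[b])))

        total = sum(r for _, _, r in rates)
        if total <= 0:
            t = t_end
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_end:
            t = t_end
            continue
        t += dt

        u = rng.random() * total
        for kind, payload, r in rates:
            if u < r:
                break
            u -= r
        if kind == "coal":
            idx = [i for i, d in enumerate(demes) if d == payload]
            i, j = rng.choice(len(idx), size=2, replace=False)
            i, j = idx[i], idx[j]
            branches.append((leaves[i], t - births[i]))
            branches.append((leaves[j], t - births[j]))
            leaves[i] = leaves[i] + leaves[j]
            births[i] = t
            for arr in (demes, births, leaves):
                arr[j] = arr[-1]
                arr.pop()
        else:
            a, b = payload
            idx = [i for i, d in enumerate(demes) if d in (a, b)]
            i = idx[int(rng.integers(len(idx)))]
            demes[i] = b if demes[i] == a else a
    return branches


@njit(cache=True)
def _accumulate_kernel(seed, n_reps, n1, n2, n3, nu_wn, nu_ea, nu_eb, nu_e,
                       T1, T2, m_wn_ea, m_wn_eb, m_ea_eb, m_wn_e, out):
    np.random.seed(seed)
    ntot = n1 + n2 + n3
    deme = np.empty(ntot, np.int64)
    cnt = np.empty((ntot, 3), np.int64)
    for _ in range(n_reps):
        k = ntot
        for i in range(ntot):
            if i < n1:
                deme[i] = 0
            elif i < n1 + n2:
                deme[i] = 1
            else:
                deme[i] = 2
            cnt[i, 0] = 1 if i < n1 else 0
            cnt[i, 1] = 1 if n1 <= i < n1 + n2 else 0
            cnt[i, 2] = 1 if i >= n1 + n2 else 0
        t = 0.0
        phase = 0
        while k > 1:
            if phase == 0 and t >= T2:
                for i in range(k):
                    if deme[i] == 2:
                        deme[i] = 1
                phase = 1
            if phase <= 1 and t >= T1:
                for i in range(k):
                    deme[i] = 0
                phase = 2

            k0 = 0
            k1 = 0
            k2 = 0
            for i in range(k):
                if deme[i] == 0:
                    k0 += 1
                elif deme[i] == 1:
                    k1 += 1
                else:
                    k2 += 1

            if phase == 0:
                r_c0 = k0 * (k0 - 1) / 2.0 / nu_wn
                r_c1 = k1 * (k1 - 1) / 2.0 / nu_ea
                r_c2 = k2 * (k2 - 1) / 2.0 / nu_eb
                r_m01 = m_wn_ea / 2.0 * (k0 + k1)
                r_m02 = m_wn_eb / 2.0 * (k0 + k2)
                r_m12 = m_ea_eb / 2.0 * (k1 + k2)
                t_end = T2
            elif phase == 1:
                r_c0 = k0 * (k0 - 1) / 2.0 / nu_wn
                r_c1 = k1 * (k1 - 1) / 2.0 / nu_e
                r_c2 = 0.0
                r_m01 = m_wn_e / 2.0 * (k0 + k1)
                r_m02 = 0.0
                r_m12 = 0.0
                t_end = T1
            else:
                r_c0 = k * (k - 1) / 2.0
                r_c1 = 0.0
                r_c2 = 0.0
                r_m01 = 0.0
                r_m02 = 0.0
                r_m12 = 0.0
                t_end = 1.0e300

            total = r_c0 + r_c1 + r_c2 + r_m01 + r_m02 + r_m12
            if total <= 0.0:
                for i in range(k):
                    out[cnt[i, 0], cnt[i, 1], cnt[i, 2]] += t_end - t
                t = t_end
                continue
            dt = -math.log(np.random.random()) / total
            if t + dt >= t_end:
                for i in range(k):
                    out[cnt[i, 0], cnt[i, 1], cnt[i, 2]] += t_end - t
                t = t_end
                continue
            for i in range(k):
                out[cnt[i, 0], cnt[i, 1], cnt[i, 2]] += dt
            t += dt

            u = np.random.random() * total
            if u < r_c0 + r_c1 + r_c2:
                if u < r_c0:
                    d = 0
                elif u < r_c0 + r_c1:
                    d = 1
                else:
                    d = 2
                kd = k0 if d == 0 else (k1 if d == 1 else k2)
                a = int(np.random.random() * kd)
                b = a
                while b == a:
                    b = int(np.random.random() * kd)
                # map within-deme ranks to lineage slots
                ia = -1
                ib = -1
                r = 0
                for i in range(k):
                    if deme[i] == d:
                        if r == a:
                            ia = i
                        if r == b:
                            ib = i
                        r += 1
                cnt[ia, 0] += cnt[ib, 0]
                cnt[ia, 1] += cnt[ib, 1]
                cnt[ia, 2] += cnt[ib, 2]
                deme[ib] = deme[k - 1]
                cnt[ib, 0] = cnt[k - 1, 0]
                cnt[ib, 1] = cnt[k - 1, 1]
                cnt[ib, 2] = cnt[k - 1, 2]
                k -= 1
            else:
                u -= r_c0 + r_c1 + r_c2
                if u < r_m01:
                    a = 0
                    b = 1
                elif u < r_m01 + r_m02:
                    a = 0
                    b = 2
                else:
                    a = 1
                    b = 2
                kab = 0
                for i in range(k):
                    if deme[i] == a or deme[i] == b:
                        kab += 1
                pick = int(np.random.random() * kab)
                r = 0
                for i in range(k):
                    if deme[i] == a or deme[i] == b:
                        if r == pick:
                            deme[i] = b if deme[i] == a else a
                            break
                        r += 1


def accumulate_branch_lengths(params, n_chrom, n_genealogies, seed):
    """Mean branch length per joint-SFS cell over ``n_genealogies`` genealogies.

    Returns an array of shape (n1+1, n2+1, n3+1) (chromosome counts per
    population); entry [i, j, k] is the mean total length (in 2*N_ref
    generations) of branches whose mutations would produce a site with
    derived counts (i, j, k).  Deterministic given ``seed``.
    """
    n1, n2, n3 = (int(n) for n in n_chrom)
    if n1 + n2 + n3 < 2:
        raise ValueError("need at least two sampled chromosomes")
    if n_genealogies < 1:
        raise ValueError("n_genealogies must be >= 1")
    params.validate()
    out = np.zeros((n1 + 1, n2 + 1, n3 + 1), dtype=np.float64)
    _accumulate_kernel(
        int(seed) % (2**32), int(n_genealogies), n1, n2, n3,
        float(params.nu_WN), float(params.nu_EA), float(params.nu_EB),
        float(params.nu_E), float(params.T1), float(params.T2),
        float(params.M_WN_EA), float(params.M_WN_EB), float(params.M_EA_EB),
        float(params.M_WN_E), out)
    out /= n_genealogies
    return out
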