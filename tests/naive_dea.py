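"""Independent brute-force formulation of the dynamic network SBM program.

Used only as a test oracle: constraints are enumerated naively with named
variables held in dictionaries, assembled into a dense matrix at the end,
and solved directly.  The construction deliberately shares no code with
dndea.engine.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def naive_overall_score(ds, o, rts="CRS", link_continuity=True, carry_continuity=True):
    """Overall efficiency of DMU ``o`` by direct enumeration.

    Uniform period/division weights.  Links: as_input charged to the
    receiving division, as_output supplied by the emitting division.
    Carry-overs use the start-of-interval observation.
    """
    names = []          # ordered variable names
    free_vars = set()
    cons = []           # (dict name -> coeff, rhs)
    obj = {}            # name -> objective coefficient (to be minimised)

    def var(name, free=False):
        if name not in names:
            names.append(name)
            if free:
                free_vars.add(name)
        return name

    K = ds.divisions
    T = ds.periods
    W = 1.0 / len(T)
    wk = 1.0 / len(K)

    # denominator per division: own inputs + received as-input links + bad carries
    den = {}
    for k in K:
        n_in = sum(1 for v in ds.variables if v.role == "input" and v.division == k)
        n_li = sum(1 for v in ds.variables if v.role == "link" and v.link_mode == "as_input" and v.link_target == k)
        n_bad = sum(1 for v in ds.variables if v.role == "carry_over" and v.carry_class == "bad" and v.division == k)
        den[k] = n_in + n_li + n_bad

    for k in K:
        for t in T:
            for v in ds.variables:
                if v.role == "input" and v.division == k:
                    row = {var(f"lam_{j}_{k}_{t}"): ds.value(j, v.name, t) for j in ds.dmu_ids}
                    s = var(f"sm_{v.name}_{k}_{t}")
                    row[s] = 1.0
                    cons.append((row, ds.value(o, v.name, t)))
                    obj[s] = -W * wk / (den[k] * ds.value(o, v.name, t))
                if v.role == "output" and v.division == k:
                    row = {var(f"lam_{j}_{k}_{t}"): ds.value(j, v.name, t) for j in ds.dmu_ids}
                    row[var(f"sp_{v.name}_{k}_{t}")] = -1.0
                    cons.append((row, ds.value(o, v.name, t)))
            if rts == "VRS":
                cons.append(({var(f"lam_{j}_{k}_{t}"): 1.0 for j in ds.dmu_ids}, 1.0))

    for v in ds.variables:
        if v.role == "link":
            for t in T:
                z_o = ds.value(o, v.name, t)
                if v.link_mode == "as_input":
                    row = {var(f"lam_{j}_{v.link_target}_{t}"): ds.value(j, v.name, t) for j in ds.dmu_ids}
                    s = var(f"sli_{v.name}_{t}")
                    row[s] = 1.0
                    cons.append((row, z_o))
                    obj[s] = -W * wk / (den[v.link_target] * z_o)
                elif v.link_mode == "as_output":
                    row = {var(f"lam_{j}_{v.link_source}_{t}"): ds.value(j, v.name, t) for j in ds.dmu_ids}
                    row[var(f"slo_{v.name}_{t}")] = -1.0
                    cons.append((row, z_o))
                elif v.link_mode == "free":
                    row = {var(f"lam_{j}_{v.link_target}_{t}"): ds.value(j, v.name, t) for j in ds.dmu_ids}
                    row[var(f"slf_{v.name}_{t}", free=True)] = 1.0
                    cons.append((row, z_o))
                else:  # fixed
                    row = {var(f"lam_{j}_{v.link_target}_{t}"): ds.value(j, v.name, t) for j in ds.dmu_ids}
                    cons.append((row, z_o))
                if link_continuity:
                    row = {}
                    for j in ds.dmu_ids:
                        row[var(f"lam_{j}_{v.link_source}_{t}")] = ds.value(j, v.name, t)
                        row[var(f"lam_{j}_{v.link_target}_{t}")] = row.get(var(f"lam_{j}_{v.link_target}_{t}"), 0.0) - ds.value(j, v.name, t)
                    cons.append((row, 0.0))

    for v in ds.variables:
        if v.role == "carry_over":
            k = v.division
            for p in range(len(T) - 1):
                t = T[p]
                z_o = ds.value(o, v.name, t)
                row = {var(f"lam_{j}_{k}_{t}"): ds.value(j, v.name, t) for j in ds.dmu_ids}
                if v.carry_class == "bad":
                    s = var(f"scb_{v.name}_{t}")
                    row[s] = 1.0
                    if z_o > 0:
                        obj[s] = -W * wk / (den[k] * z_o)
                elif v.carry_class == "good":
                    row[var(f"scg_{v.name}_{t}")] = -1.0
                elif v.carry_class == "free":
                    row[var(f"scf_{v.name}_{t}", free=True)] = 1.0
                cons.append((row, z_o))
                if carry_continuity:
                    row = {}
                    for j in ds.dmu_ids:
                        row[var(f"lam_{j}_{k}_{t}")] = ds.value(j, v.name, t)
                        nxt = var(f"lam_{j}_{k}_{T[p+1]}")
                        row[nxt] = row.get(nxt, 0.0) - ds.value(j, v.name, t)
                    cons.append((row, 0.0))

    idx = {n: i for i, n in enumerate(names)}
    A = np.zeros((len(cons), len(names)))
    b = np.zeros(len(cons))
    for r, (row, rhs) in enumerate(cons):
        for n, coeff in row.items():
            A[r, idx[n]] = coeff
        b[r] = rhs
    c = np.zeros(len(names))
    for n, coeff in obj.items():
        c[idx[n]] = coeff
    bounds = [((None, None) if n in free_vars else (0.0, None)) for n in names]
    res = linprog(c, A_eq=A, b_eq=b, bounds=bounds, method="highs")
    assert res.status == 0, res.message
    return 1.0 + res.fun
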