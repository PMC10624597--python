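"""Low-level mass-action rate-law kernels.

A compiled network is flattened into index arrays so the right-hand side
and Jacobian can be evaluated in tight loops:

- ``term_ptr``/``term_species``/``term_order``: CSR-style layout of the
  kinetic terms of each reaction (reactants with their stoichiometric
  order plus catalytic modifiers with their declared order).
- ``stoich_ptr``/``stoich_species``/``stoich_coef``: CSR-style layout of
  the nonzero stoichiometric-matrix entries of each reaction.

If numba is importable the kernels are JIT-compiled; otherwise identical
pure-Python versions are used.
"""

from __future__ import annotations

import numpy as np

try:  # numba is an optional accelerator, never a hard dependency
    from numba import njit as _njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=True)
def rhs_kernel(y, k, term_ptr, term_species, term_order,
               stoich_ptr, stoich_species, stoich_coef, out):
    n_r = k.shape[0]
    out[:] = 0.0
    for j in range(n_r):
        f = k[j]
        for t in range(term_ptr[j], term_ptr[j + 1]):
            f *= y[term_species[t]] ** term_order[t]
        for s in range(stoich_ptr[j], stoich_ptr[j + 1]):
            out[stoich_species[s]] += stoich_coef[s] * f
    return out


@_njit(cache=True)
def jac_kernel(y, k, term_ptr, term_species, term_order,
               stoich_ptr, stoich_species, stoich_coef, out):
    n_r = k.shape[0]
    out[:, :] = 0.0
    for j in range(n_r):
        for t in range(term_ptr[j], term_ptr[j + 1]):
            # d(flux_j)/d(y_i) for the species of kinetic term t
            d = k[j] * term_order[t] * y[term_species[t]] ** (term_order[t] - 1.0)
            for u in range(term_ptr[j], term_ptr[j + 1]):
                if u != t:
                    d *= y[term_species[u]] ** term_order[u]
            col = term_species[t]
            for s in range(stoich_ptr[j], stoich_ptr[j + 1]):
                out[stoich_species[s], col] += stoich_coef[s] * d
    return out


@_njit(cache=True)
def rk4_kernel(y0, k, term_ptr, term_species, term_order,
               stoich_ptr, stoich_species, stoich_coef,
               dt, n_steps, sample_every, samples):
    """Fixed-step classical 4th-order Runge-Kutta; oracle integrator."""
    n_s = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(n_s)
    k2 = np.empty(n_s)
    k3 = np.empty(n_s)
    k4 = np.empty(n_s)
    tmp = np.empty(n_s)
    samples[0, :] = y
    row = 1
    for step in range(n_steps):
        rhs_kernel(y, k, term_ptr, term_species, term_order,
                   stoich_ptr, stoich_species, stoich_coef, k1)
        for i in range(n_s):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        rhs_kernel(tmp, k, term_ptr, term_species, term_order,
                   stoich_ptr, stoich_species, stoich_coef, k2)
        for i in range(n_s):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        rhs_kernel(tmp, k, term_ptr, term_species, term_order,
                   stoich_ptr, stoich_species, stoich_coef, k3)
        for i in range(n_s):
            tmp[i] = y[i] + dt * k3[i]
        rhs_kernel(tmp, k, term_ptr, term_species, term_order,
                   stoich_ptr, stoich_species, stoich_coef, k4)
        for i in range(n_s):
            y[i] = y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % sample_every == 0:
            samples[row, :] = y
            row += 1
    return samples
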