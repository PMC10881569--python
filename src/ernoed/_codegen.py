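"""Generate fast scalar kernels for the kinetics from sympy expressions.

``sympy.lambdify`` builds a nested list and converts it to an array on
every call, which dominates the cost of ODE right-hand sides.  Here the
flux vector, the reaction part of dC/dt and its two Jacobians are emitted
as flat scalar assignments into preallocated output arrays and, when
numba is importable, JIT-compiled.  The pure-Python fallback keeps the
package functional without numba (just slower).
"""

from __future__ import annotations

import math

import numpy as np
import sympy as sp
from sympy.printing.pycode import PythonCodePrinter

try:  # pragma: no cover - exercised implicitly everywhere
    import numba
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    numba = None
    HAVE_NUMBA = False

_printer = PythonCodePrinter({"fully_qualified_modules": False})


def _emit_function(name: str, exprs, out_shape, subs: dict) -> str:
    """Source for ``name(c, th, ld, out)`` filling ``out`` (flattened)."""
    flat = [e.xreplace(subs) for e in exprs]
    temps, reduced = sp.cse(flat, optimizations="basic")
    lines = [f"def {name}(c, th, ld, out):"]
    for sym, expr in temps:
        lines.append(f"    {sym} = {_printer.doprint(expr)}")
    for i, expr in enumerate(reduced):
        lines.append(f"    out[{i}] = {_printer.doprint(expr)}")
    lines.append("    return out")
    return "\n".join(lines)


def build_kernels(c_syms, p_syms, l_syms, rates_mat, f_mat, jac_mat,
                  dfdth_mat):
    """Compile the four kinetics kernels; returns a dict of callables.

    Every kernel has signature ``kernel(c, theta, load, out)`` with ``out``
    a preallocated 1-D float array (row-major flattening for matrices).
    """
    subs = {}
    for i, s in enumerate(c_syms):
        subs[s] = sp.Symbol(f"_c{i}")
    for i, s in enumerate(p_syms):
        subs[s] = sp.Symbol(f"_t{i}")
    for i, s in enumerate(l_syms):
        subs[s] = sp.Symbol(f"_l{i}")

    def header() -> list[str]:
        lines = []
        for i in range(len(c_syms)):
            lines.append(f"    _c{i} = c[{i}]")
        for i in range(len(p_syms)):
            lines.append(f"    _t{i} = th[{i}]")
        for i in range(len(l_syms)):
            lines.append(f"    _l{i} = ld[{i}]")
        return lines

    sources = {}
    for name, mat in (("rates", rates_mat), ("f", f_mat),
                      ("jac_c", jac_mat), ("dfdtheta", dfdth_mat)):
        src = _emit_function(name, list(mat), mat.shape, subs)
        body = src.split("\n")
        src = "\n".join([body[0]] + header() + body[1:])
        sources[name] = src

    namespace = {"math": math, "sqrt": math.sqrt}
    kernels = {}
    for name, src in sources.items():
        local: dict = {}
        exec(compile(src, f"<ernoed-kernel-{name}>", "exec"),
             dict(namespace), local)
        fn = local[name]
        if HAVE_NUMBA:
            # IEEE error model: a trial integrator step may cross a
            # denominator zero; the solver rejects the step on inf/nan
            fn = numba.njit(fn, fastmath=False, cache=False,
                            error_model="numpy")
        kernels[name] = fn
    return kernels
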