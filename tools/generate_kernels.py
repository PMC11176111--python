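"""Regenerate src/tcellca/_kernels.py from the symbolic model.

The kernels are plain scalar-math Python functions (numba-jitted when
available) for the right-hand sides, state Jacobians and the full
parameter-derivative matrices of both models. Run from the repo root:

    python tools/generate_kernels.py
"""

from pathlib import Path

import sympy as sp

import sys
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from tcellca._jacobian import _symbolic, _PARAM_NAMES  # noqa: E402


def emit_function(name, exprs, shape, state_syms, par_syms, lines):
    """Append one generated function; exprs is a flat list (row-major)."""
    repl, reduced = sp.cse(exprs, optimizations="basic")
    lines.append("@njit(cache=False)" if True else "")
    args = "y, pv"
    lines.append(f"def {name}({args}):")
    for i, s in enumerate(state_syms):
        lines.append(f"    {s} = y[{i}]")
    for i, s in enumerate(par_syms):
        lines.append(f"    {s} = pv[{i}]")
    printer = sp.printing.pycode
    for sym, expr in repl:
        lines.append(f"    {sym} = {printer(expr)}")
    total = 1
    for d in shape:
        total *= d
    lines.append(f"    out = np.empty({total})")
    for k, expr in enumerate(reduced):
        lines.append(f"    out[{k}] = {printer(expr)}")
    if len(shape) == 2:
        lines.append(f"    return out.reshape({shape[0]}, {shape[1]})")
    else:
        lines.append("    return out")
    lines.append("")
    lines.append("")


def main():
    (c, ce, h, p, s), par, f_open, f_closed = _symbolic()
    par_syms = [par[nm] for nm in _PARAM_NAMES]
    open_syms = [c, ce, h, p, s]
    closed_syms = [c, h, p]

    lines = [
        '"""Generated scalar kernels for the Ca2+ models.',
        "",
        "Auto-generated by tools/generate_kernels.py from the symbolic model",
        "definition; do not edit by hand. Each function takes the state",
        "vector y and the parameter vector pv (ordering in PARAM_ORDER).",
        '"""',
        "",
        "import math",
        "",
        "import numpy as np",
        "",
        "try:",
        "    from numba import njit",
        "except ImportError:  # pragma: no cover - numba is an optional speed-up",
        "    def njit(*a, **k):",
        "        def wrap(f):",
        "            return f",
        "        return wrap",
        "",
        f"PARAM_ORDER = {tuple(_PARAM_NAMES)!r}",
        "",
        "",
    ]

    for model, fvec, syms in (("open", f_open, open_syms),
                              ("closed", f_closed, closed_syms)):
        n = len(syms)
        J = fvec.jacobian(syms)
        D = fvec.jacobian(par_syms)   # (n, n_par)
        emit_function(f"rhs_{model}", list(fvec), (n,), syms, par_syms, lines)
        emit_function(f"jac_{model}", [J[i, j] for i in range(n)
                                       for j in range(n)], (n, n),
                      syms, par_syms, lines)
        emit_function(f"dpar_{model}", [D[i, j] for i in range(n)
                                        for j in range(len(par_syms))],
                      (n, len(par_syms)), syms, par_syms, lines)

    # augmented variational kernels assembled from the pieces
    for model, n in (("open", 5), ("closed", 3)):
        lines += [
            "@njit(cache=False)",
            f"def rhs_var_{model}(z, pv, ip):",
            f"    n = {n}",
            "    x = z[:n]",
            f"    f = rhs_{model}(x, pv)",
            f"    J = jac_{model}(x, pv)",
            "    out = np.empty(z.size)",
            "    out[:n] = f",
            "    Phi = np.ascontiguousarray(z[n:n + n * n]).reshape(n, n)",
            "    out[n:n + n * n] = (J @ Phi).ravel()",
            "    if z.size > n + n * n:",
            f"        dp = dpar_{model}(x, pv)",
            "        out[n + n * n:] = J @ z[n + n * n:] + dp[:, ip]",
            "    return out",
            "",
            "",
        ]

    text = "\n".join(lines)
    out = Path(__file__).resolve().parents[1] / "src/tcellca/_kernels.py"
    out.write_text(text)
    print(f"wrote {out} ({len(text)} bytes)")


if __name__ == "__main__":
    main()
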