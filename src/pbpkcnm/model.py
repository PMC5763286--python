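"""Whole-body PBPK forward model for irinotecan and its metabolites.

Five compounds (CPT-11, SN-38, SN-38G, NPC, APC) move through 16 circulatory
compartments plus seven elimination compartments (three biliary transit,
small- and large-intestinal lumen, urine, feces).  Tissue exchange is
perfusion-limited: each tissue receives arterial blood at flow Q and
equilibrates instantly, so the emergent (venous) concentration is
C_tissue / Kp.  The lung sits in series between the venous and arterial
pools; the splanchnic organs drain to the liver inlet.  Renal clearance acts
on kidney outflow plasma, biliary and metabolic clearances on liver outflow
plasma.  Bile passes through a three-compartment transit chain into the
small-intestinal lumen, from which drug is reabsorbed into the liver at k_a
(enterohepatic circulation) or passed on to the large-intestinal lumen and
feces.  Lumenal SN-38G is deconjugated by gut-flora β-glucuronidase, so its
absorbed fraction re-enters the liver as SN-38.

With first-order kinetics throughout, the state equation is linear,
dx/dt = M x + u(t), with a zero-order infusion u active during
[0, infusion_duration].  The default integrator propagates the system with
the matrix exponential of M — exact for a linear system regardless of
stiffness; a stiff implicit ODE solver (BDF) is available for cross-checks.

Amounts are μg per kg body weight; concentrations are amount / volume
(= μg/ml, volumes being ml/kg); metabolite conversion is 1:1 in these
dose-equivalent units with no molecular-weight correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .parameters import SPECIES, DrugParameterSet
from .physiology import KP_ORGANS, ORGANS, SPLANCHNIC, VENOUS_RETURN, PatientPhysiology

__all__ = [
    "COMPARTMENTS",
    "N_STATE",
    "OBSERVABLE_NAMES",
    "state_index",
    "build_linear_system",
    "assemble_rhs",
    "simulate",
    "SimulationResult",
    "compute_observables",
]

#: All 23 model compartments: 16 circulatory + 7 elimination/transit.
COMPARTMENTS = ORGANS + ("bile_1", "bile_2", "bile_3", "si_lumen", "li_lumen",
                         "urine", "feces")

N_SPECIES = len(SPECIES)
N_STATE = len(COMPARTMENTS) * N_SPECIES  # 115

_C = {name: i for i, name in enumerate(COMPARTMENTS)}
_S = {name: i for i, name in enumerate(SPECIES)}

#: The 13 observables, in objective-vector order: urinary cumulative
#: excretion (% of dose) for all five compounds, fecal cumulative excretion
#: for CPT-11, SN-38 + SN-38G combined, NPC and APC, and venous Cmax (μg/ml)
#: for CPT-11, SN-38, SN-38G and APC.
OBSERVABLE_NAMES = (
    "urine_CPT-11", "urine_SN-38", "urine_SN-38G", "urine_NPC", "urine_APC",
    "feces_CPT-11", "feces_SN-38+SN-38G", "feces_NPC", "feces_APC",
    "cmax_CPT-11", "cmax_SN-38", "cmax_SN-38G", "cmax_APC",
)


def state_index(compartment: str, species: str) -> int:
    """Position of one (compartment, compound) amount in the state vector."""
    return _C[compartment] * N_SPECIES + _S[species]


def build_linear_system(
    phys: PatientPhysiology, params: DrugParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the rate matrix M and the unit infusion direction u.

    Returns ``(M, u)`` with dx/dt = M x + rate(t) * u, where u is the unit
    vector on venous-blood CPT-11 and rate(t) = dose / infusion_duration
    during the infusion, 0 after.  Every transfer appears once as a loss and
    once as a gain, so the columns of M sum to zero exactly (mass
    conservation); flows are rebalanced via
    :meth:`PatientPhysiology.balanced_flows` so that a spatially uniform
    concentration is a true equilibrium of the distribution-only system.
    """
    M = np.zeros((N_STATE, N_STATE))
    q = phys.balanced_flows()
    v = phys.volume
    q_liver = q["liver_total"]
    q_portal_in = {o: q[o] for o in SPLANCHNIC}

    def add(dst: int | None, src: int, rate_per_amount: float) -> None:
        # first-order transfer src -> dst (dst None: pure check, unused)
        M[src, src] -= rate_per_amount
        if dst is not None:
            M[dst, src] += rate_per_amount

    for s in SPECIES:
        si = _S[s]

        def idx(c: str) -> int:
            return state_index(c, s)

        def out_rate(organ: str, flow: float) -> float:
            # venous-equilibrated outflow: flow * C/Kp per unit amount
            return flow / (v[organ] * params.kp(organ, s))

        ven, art = idx("venous_blood"), idx("artery_blood")
        # venous -> lung -> arterial
        add(idx("lung"), ven, q["lung"] / v["venous_blood"])
        add(art, idx("lung"), out_rate("lung", q["lung"]))
        # arterial supply of every non-lung perfused organ; the liver
        # receives only its hepatic-artery share from the arterial pool
        for organ in VENOUS_RETURN + SPLANCHNIC:
            flow = q["liver_artery"] if organ == "liver" else q[organ]
            add(idx(organ), art, flow / v["artery_blood"])
        # venous return of non-splanchnic tissues (liver handled below)
        for organ in VENOUS_RETURN:
            if organ == "liver":
                continue
            add(ven, idx(organ), out_rate(organ, q[organ]))
        # splanchnic outflow feeds the liver inlet (portal vein)
        for organ, flow in q_portal_in.items():
            add(idx("liver"), idx(organ), out_rate(organ, flow))
        # liver venous outflow at the total (artery + portal) flow
        add(ven, idx("liver"), out_rate("liver", q_liver))
        # renal elimination from kidney outflow plasma
        add(idx("urine"), idx("kidney"), out_rate("kidney", params.cl_r(s)))
        # biliary elimination from liver outflow plasma, then transit chain
        add(idx("bile_1"), idx("liver"), out_rate("liver", params.cl_bile(s)))
        kb = params.k_bile(s)
        add(idx("bile_2"), idx("bile_1"), kb)
        add(idx("bile_3"), idx("bile_2"), kb)
        add(idx("si_lumen"), idx("bile_3"), kb)
        # lumenal fate: reabsorption to liver, transit to colon, then feces
        ka = params.k_a(s)
        if s == "SN-38G":
            # deconjugated on absorption: lumenal SN-38G returns as SN-38
            add(state_index("liver", "SN-38"), idx("si_lumen"), ka)
        else:
            add(idx("liver"), idx("si_lumen"), ka)
        add(idx("li_lumen"), idx("si_lumen"), params.k_li(s))
        add(idx("feces"), idx("li_lumen"), params.k_feces(s))

    # hepatic metabolism: clearances act on liver outflow plasma of the
    # parent and deposit 1:1 into the liver pool of the product
    def met(parent: str, product: str, cl: float) -> None:
        rate = cl / (v["liver"] * params.kp("liver", parent))
        add(state_index("liver", product), state_index("liver", parent), rate)

    met("CPT-11", "SN-38", params.cl_met("CL_CES1"))
    met("CPT-11", "APC", params.cl_met("CL_3A4_1"))
    met("CPT-11", "NPC", params.cl_met("CL_3A4_2"))
    met("NPC", "SN-38", params.cl_met("CL_CES2"))
    met("SN-38", "SN-38G", params.cl_met("CL_UGT"))

    u = np.zeros(N_STATE)
    u[state_index("venous_blood", "CPT-11")] = 1.0
    return M, u


def assemble_rhs(phys: PatientPhysiology, params: DrugParameterSet):
    """Return f(t, x) = M x + rate(t) u for use with an ODE solver."""
    M, u = build_linear_system(phys, params)
    rate = phys.dose / phys.infusion_duration
    t_inf = phys.infusion_duration

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        dx = M @ x
        if t < t_inf:
            dx = dx + rate * u
        return dx

    return rhs


@dataclass
class SimulationResult:
    """Trajectory and summary observables of one forward simulation."""

    times: np.ndarray  # min, shape (nt,)
    amounts: np.ndarray  # μg/kg, shape (nt, 23, 5)
    phys: PatientPhysiology
    status: str = "ok"  # "ok" | "failed"
    cmax_window: float = 0.0  # min; venous Cmax searched on [0, window]

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def venous_concentration(self) -> np.ndarray:
        """Venous blood concentration trace, μg/ml, shape (nt, 5)."""
        return self.amounts[:, _C["venous_blood"], :] / self.phys.volume["venous_blood"]

    @property
    def cmax(self) -> np.ndarray:
        """Per-compound peak venous concentration within the search window."""
        in_window = self.times <= self.cmax_window + 1e-9
        return self.venous_concentration[in_window].max(axis=0)

    @property
    def cumulative_urine(self) -> np.ndarray:
        """Cumulative urinary excretion at the horizon, % of dose, per compound."""
        return self.amounts[-1, _C["urine"], :] / self.phys.dose * 100.0

    @property
    def cumulative_feces(self) -> np.ndarray:
        """Cumulative fecal excretion at the horizon, % of dose, per compound."""
        return self.amounts[-1, _C["feces"], :] / self.phys.dose * 100.0

    def infused(self, t: np.ndarray | float) -> np.ndarray:
        """Cumulative infused CPT-11 amount (μg/kg) at time(s) t."""
        rate = self.phys.dose / self.phys.infusion_duration
        return rate * np.minimum(np.asarray(t, dtype=float), self.phys.infusion_duration)

    def mass_balance_residual(self) -> float:
        """max_t | total amount in the system − cumulative infused |, μg/kg."""
        total = self.amounts.sum(axis=(1, 2))
        return float(np.max(np.abs(total - self.infused(self.times))))


def simulate(
    phys: PatientPhysiology,
    params: DrugParameterSet,
    horizon: float = 30_240.0,
    method: str = "expm",
    rtol: float = 1e-6,
    atol_scale: float = 1e-9,
) -> SimulationResult:
    """Run one forward simulation and return the trajectory.

    Parameters
    ----------
    horizon
        End of integration in minutes (default 21 days, by which terminal
        excretion flux is negligible for parameters within the estimation
        bounds); must be at least the infusion duration.
    method
        ``"expm"`` (exact matrix-exponential propagation, default) or
        ``"bdf"`` (stiff implicit ODE solver on the same grid).
    rtol, atol_scale
        Tolerances for the BDF route; absolute tolerance is
        ``atol_scale * dose``.  Ignored by ``"expm"``.

    The output grid is 1-min spaced through four infusion durations (the
    venous Cmax search window) and sparser beyond.
    """
    if horizon < phys.infusion_duration:
        raise ValueError("horizon must cover the infusion")
    M, u = build_linear_system(phys, params)
    rate = phys.dose / phys.infusion_duration
    t_inf = phys.infusion_duration
    fine_until = min(4.0 * t_inf, horizon)
    cmax_window = fine_until

    if method == "expm":
        if abs(t_inf - round(t_inf)) > 1e-9:
            raise ValueError("expm propagation steps in whole minutes; "
                             "use method='bdf' for fractional infusion durations")
        n = M.shape[0]
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = M
        aug[:n, n] = u
        try:
            E_aug = expm(aug)
        except Exception:
            return SimulationResult(np.zeros(1), np.zeros((1, len(COMPARTMENTS), N_SPECIES)),
                                    phys, status="failed", cmax_window=cmax_window)
        E, f = E_aug[:n, :n], E_aug[:n, n]
        times = [0.0]
        states = [np.zeros(n)]
        x = states[0]
        t = 0.0
        for _ in range(int(round(fine_until))):
            x = E @ x + (rate * f if t < t_inf - 1e-9 else 0.0)
            t += 1.0
            times.append(t)
            states.append(x)
        # cover the remainder with binary powers of the 1-min propagator
        remaining = int(round(horizon - t))
        P = E
        step = 1
        while remaining > 0:
            if remaining & 1:
                x = P @ x
                t += step
                times.append(t)
                states.append(x)
            remaining >>= 1
            if remaining:
                P = P @ P
                step *= 2
        traj = np.vstack(states)
        if not np.all(np.isfinite(traj)):
            return SimulationResult(np.zeros(1), np.zeros((1, len(COMPARTMENTS), N_SPECIES)),
                                    phys, status="failed", cmax_window=cmax_window)
        amounts = traj.reshape(len(times), len(COMPARTMENTS), N_SPECIES)
        return SimulationResult(np.asarray(times), amounts, phys, cmax_window=cmax_window)

    if method != "bdf":
        raise ValueError(f"unknown method: {method!r}")

    atol = atol_scale * max(phys.dose, 1.0)
    fine = np.arange(0.0, fine_until + 0.5)
    coarse = np.geomspace(max(fine_until, 1.0), horizon, 40)[1:] if horizon > fine_until else []
    t_eval = np.unique(np.concatenate([fine, coarse, [horizon]]))
    x0 = np.zeros(N_STATE)
    # split at the infusion stop so the input discontinuity never crosses a step
    seg1 = t_eval[t_eval <= t_inf]
    if seg1[-1] < t_inf:
        seg1 = np.append(seg1, t_inf)
    sol1 = solve_ivp(lambda t, x: M @ x + rate * u, (0.0, t_inf), x0,
                     method="BDF", t_eval=seg1, rtol=rtol, atol=atol,
                     jac=lambda t, x: M)
    if not sol1.success:
        return SimulationResult(np.zeros(1), np.zeros((1, len(COMPARTMENTS), N_SPECIES)),
                                phys, status="failed", cmax_window=cmax_window)
    seg2 = t_eval[t_eval > t_inf]
    sol2 = solve_ivp(lambda t, x: M @ x, (t_inf, horizon), sol1.y[:, -1],
                     method="BDF", t_eval=seg2, rtol=rtol, atol=atol,
                     jac=lambda t, x: M)
    if not sol2.success:
        return SimulationResult(np.zeros(1), np.zeros((1, len(COMPARTMENTS), N_SPECIES)),
                                phys, status="failed", cmax_window=cmax_window)
    times = np.concatenate([sol1.t, sol2.t])
    traj = np.concatenate([sol1.y.T, sol2.y.T])
    amounts = traj.reshape(len(times), len(COMPARTMENTS), N_SPECIES)
    return SimulationResult(times, amounts, phys, cmax_window=cmax_window)


def compute_observables(result: SimulationResult, dose: float | None = None) -> np.ndarray:
    """Reduce a simulation to the 13-entry objective vector.

    Order follows :data:`OBSERVABLE_NAMES`: five urinary ratios (% of dose),
    four fecal ratios — SN-38 and SN-38G are pooled because gut-flora
    deconjugation makes them indistinguishable in feces — and four venous
    Cmax values (μg/ml; NPC is not an objective).
    """
    if not result.ok:
        raise RuntimeError("cannot compute observables from a failed simulation")
    if dose is None:
        dose = result.phys.dose
    if dose == 0:
        return np.zeros(13)
    urine = result.amounts[-1, _C["urine"], :] / dose * 100.0
    feces = result.amounts[-1, _C["feces"], :] / dose * 100.0
    cmax = result.cmax
    s = _S
    return np.array([
        urine[s["CPT-11"]], urine[s["SN-38"]], urine[s["SN-38G"]],
        urine[s["NPC"]], urine[s["APC"]],
        feces[s["CPT-11"]], feces[s["SN-38"]] + feces[s["SN-38G"]],
        feces[s["NPC"]], feces[s["APC"]],
        cmax[s["CPT-11"]], cmax[s["SN-38"]], cmax[s["SN-38G"]], cmax[s["APC"]],
    ])
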