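"""Brute-force parcel-ledger soil column for cross-checking colour tracing.

Independent of the fractional implementation: every compartment holds a
list of individually tagged water parcels (amount, colour). Inflows append
new parcels; every outflow removes water proportionally from each parcel
of the donor store, so each parcel keeps its identity while mixing
statistics emerge from the bookkeeping rather than from stored fractions.
Physical rules (curve-number runoff, tau-cascade drainage, capillary rise,
two-stage evaporation, weighted root uptake) are re-stated here from
first principles so the two code paths share no state machinery.
"""

from __future__ import annotations

import numpy as np

GREEN, BLUE_I, BLUE_CR = 0, 1, 2


class ParcelColumn:
    def __init__(self, thicknesses_m, theta_sat, theta_fc, theta_wp, tau,
                 curve_number, rew, initial_theta, initial_colour=GREEN):
        self.dz = np.asarray(thicknesses_m, dtype=float)
        self.n = len(self.dz)
        self.sat = theta_sat * self.dz * 1000.0
        self.fc = theta_fc * self.dz * 1000.0
        self.wp = theta_wp * self.dz * 1000.0
        self.tau = tau
        self.cn = curve_number
        self.rew = rew
        self.tew = max((theta_fc - 0.5 * theta_wp) * self.dz[0] * 1000.0, rew)
        self.floor0 = 0.5 * theta_wp * self.dz[0] * 1000.0
        # each compartment: list of [amount_mm, colour]
        self.parcels = [[[initial_theta * dz * 1000.0, initial_colour]]
                        for dz in self.dz]
        self.evap_depletion = 0.0
        self.cum_et = np.zeros(3)
        self.cum_out = np.zeros(3)
        self.cum_in = np.zeros(3)

    # -- bookkeeping helpers -------------------------------------------
    def _w(self, i):
        return sum(p[0] for p in self.parcels[i])

    def storage_by_colour(self):
        out = np.zeros(3)
        for comp in self.parcels:
            for amount, colour in comp:
                out[colour] += amount
        return out

    def _remove(self, i, amount):
        """Remove proportionally from every parcel of compartment i;
        returns the removed amounts per colour."""
        w = self._w(i)
        removed = np.zeros(3)
        if w <= 0 or amount <= 0:
            return removed
        f = min(amount / w, 1.0)
        for p in self.parcels[i]:
            take = p[0] * f
            p[0] -= take
            removed[p[1]] += take
        self.parcels[i] = [p for p in self.parcels[i] if p[0] > 1e-15]
        return removed

    def _add(self, i, amounts):
        for colour in (GREEN, BLUE_I, BLUE_CR):
            if amounts[colour] > 0:
                self.parcels[i].append([float(amounts[colour]), colour])

    def _route_down(self, amounts):
        """Fill compartments to saturation top-down; return deep percolation."""
        moving = np.asarray(amounts, dtype=float).copy()
        for i in range(self.n):
            total = moving.sum()
            if total <= 1e-15:
                return np.zeros(3)
            room = self.sat[i] - self._w(i)
            if room <= 0:
                continue
            take = min(total, room)
            frac = take / total
            taken = moving * frac
            self._add(i, taken)
            moving -= taken
        return moving

    # -- one day --------------------------------------------------------
    def step(self, precip, et0, cc, root_depth, irrigation,
             water_table_depth, system="rainfed"):
        dz = self.dz
        # capillary rise (rainfed only here; linear law, dryness gated)
        if system == "rainfed":
            depth = max(water_table_depth, 1.0)
            if depth <= 4.0:
                i = self.n - 1
                w = self._w(i)
                potential = 5.0 * (4.0 - depth) / 3.0
                dry = min(max((self.fc[i] - w) / max(self.fc[i] - self.wp[i], 1e-9), 0.0), 1.0)
                flux = min(potential * dry, max(self.fc[i] - w, 0.0))
                if flux > 0:
                    self._add(i, np.array([0.0, 0.0, flux]))
                    self.cum_in[BLUE_CR] += flux

        # rainfall: curve number runoff, remainder infiltrates (green)
        if precip > 0:
            s = 254.0 * (100.0 / self.cn - 1.0)
            runoff = 0.0 if precip <= 0.2 * s else \
                (precip - 0.2 * s) ** 2 / (precip + 0.8 * s)
            inf = precip - runoff
            self.cum_in[GREEN] += precip
            self.cum_out[GREEN] += runoff
            dp = self._route_down(np.array([inf, 0.0, 0.0]))
            self.cum_out += dp
            self.evap_depletion = max(self.evap_depletion - inf, 0.0)

        # irrigation infiltrates as blue_i
        if irrigation > 0:
            self.cum_in[BLUE_I] += irrigation
            dp = self._route_down(np.array([0.0, irrigation, 0.0]))
            self.cum_out += dp
            self.evap_depletion = max(self.evap_depletion - irrigation, 0.0)

        # drainage cascade
        moving = np.zeros(3)
        for i in range(self.n):
            total = moving.sum()
            if total > 0:
                room = max(self.sat[i] - self._w(i), 0.0)
                take = min(total, room)
                if take > 0:
                    taken = moving * (take / total)
                    self._add(i, taken)
                    moving -= taken
            excess = self._w(i) - self.fc[i]
            if excess > 0:
                moving += self._remove(i, self.tau * excess)
        self.cum_out += moving

        # evaporation (two-stage) from the top compartment
        evap_demand = et0 * 1.1 * (1.0 - cc)
        de = self.evap_depletion
        stage1 = min(evap_demand, max(self.rew - de, 0.0))
        kr = max((self.tew - (de + stage1)) / max(self.tew - self.rew, 1e-9), 0.0)
        stage2 = (evap_demand - stage1) * min(kr, 1.0)
        supply = max(self._w(0) - self.floor0, 0.0)
        e = min(stage1 + stage2, supply)
        if e > 0:
            removed = self._remove(0, e)
            self.cum_et += removed
            self.cum_out += removed
            self.evap_depletion = de + e

        # transpiration: tapered overlap weights, two passes
        transp = et0 * 1.05 * cc
        bottoms = np.cumsum(dz)
        tops = bottoms - dz
        centres = (tops + bottoms) / 2.0
        if root_depth > 0:
            overlap = np.clip(np.minimum(bottoms, root_depth) - tops, 0.0, None)
            taper = np.clip(1.0 - 0.8 * centres / root_depth, 0.2, 1.0)
            base_w = overlap * taper
        else:
            base_w = np.zeros(self.n)
        t_left = transp
        for _ in range(2):
            if t_left <= 1e-12 or base_w.sum() <= 0:
                break
            avail = np.array([max(self._w(i) - self.wp[i], 0.0)
                              for i in range(self.n)])
            weighted = base_w * (avail > 1e-9)
            sw_ = weighted.sum()
            if sw_ <= 0:
                break
            share = t_left * weighted / sw_
            take = np.minimum(share, avail)
            for i in range(self.n):
                if take[i] > 0:
                    removed = self._remove(i, take[i])
                    self.cum_et += removed
                    self.cum_out += removed
            t_left -= take.sum()
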