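# plaquestress

Cyclic **plaque structural stress** from intravascular imaging cross-sections.

Atherosclerotic plaques fail mechanically: with every heartbeat the
intracoronary pressure wave loads the vessel wall, and the repeated stress
concentration on the thin fibrous cap of a lipid-rich plaque is a candidate
mechanism for cap fatigue and rupture. `plaquestress` estimates this cyclic
loading *per cross-section*: given the lumen and internal-elastic-lamina
(IEL) contours of an OCT-style cross-section, labelled lipid/calcium plaque
regions, media/adventitia thicknesses, paired aortic/distal pressure
tracings and an OFR (optical flow ratio, an FFR surrogate) pullback curve,
it builds a three-layer 2D finite-element model and computes the change in
plaque structural stress over the cardiac cycle. It is intended for
cardiovascular-biomechanics researchers; since no public dataset couples
OCT morphology with pressure-wire tracings, a first-class synthetic-study
generator stands in for patient data and makes every stage testable.

## Model

**Geometry.** The wall is a three-layer annulus: intima (fibrous background
with lipid/calcium inclusions) between the lumen and the IEL, plus media and
adventitia as uniform outward offsets of the IEL.

**Materials** (plane-strain finite deformation, isochoric invariants
$\bar I_1,\bar I_2,\bar I_4$; near-incompressibility via a volumetric
penalty $\tfrac{\kappa}{2}(J-1)^2$ on the averaged nodal Jacobian):

- lipid and calcium — isotropic exponential Mooney–Rivlin,
  $W = C_1(\bar I_1-3) + C_2(\bar I_2-3) + D_1\!\left(e^{D_2(\bar I_1-3)}-1\right)$
- fibrous intima, media, adventitia — two-term Holzapfel-type
  fiber-reinforced model with a circumferential fiber family,
  $W = \mu(\bar I_1-3) + \tfrac{k_1}{k_2}\!\left(e^{k_2\left[(1-\rho)(\bar I_1-3)^2 + \rho(\bar I_4-1)^2\right]}-1\right)$

**Load.** The OFR pullback is normalized between the resting aortic and
distal tracings, $P(x,t) = P_d(t) + \big(P_a(t)-P_d(t)\big)\,
\frac{\mathrm{OFR}(x)-\mathrm{OFR}_w}{\mathrm{OFR}_p-\mathrm{OFR}_w}$,
giving the pressure waveform at each pullback position. The solver is driven
by the **relative pressure** $\Delta p(t) = P(x,t) - \min_t P(x,t)$ (in kPa),
so the imaged diastolic geometry is the stress-free reference and no
zero-pressure-state reconstruction is needed. $\Delta p$ acts as a follower
load on the deformed lumen boundary; rigid-body translation and rotation are
removed by Lagrange constraints.

**Endpoints.**

- **ΔPSS** — maximal superficial von Mises stress (elements within 50 µm of
  the lumen) at peak load, in kPa;
- **LDC / LDC%** — cycle change of the area-equivalent lumen diameter
  $d = 2\sqrt{A/\pi}$, absolute (mm) and relative to the minimal diameter.

## Worked example

```bash
python examples/03_single_section_stress.py
```

```
mesh: 1658 nodes, 2996 triangles, 481 superficial (<50 um) elements
dPSS  =   33.6 kPa at (-0.69, -0.14) mm
LDC   =  0.144 mm
LDC%  =   7.21 %
```

A synthetic fibroatheroma (lumen radius 1 mm, 0.8 mm eccentric wall, 110°
lipid pool under a 150 µm cap) under a 5 kPa cyclic load concentrates
33.6 kPa of superficial stress on the fibrous cap, while the lumen diameter
swings by 7.2% of its diastolic value. Sweeping only the cap thickness
(`examples/04_cap_thickness_sweep.py`) shows the hallmark mechanism — the
same section yields 25.0 → 62.7 kPa as the cap thins from 250 to 50 µm.
Other examples build the layered geometry, derive position-specific loads,
and run the full per-lesion pipeline; a thin CLI (`plaquestress synth / run /
summarize`) wraps the same functions for shell use.

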