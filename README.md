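# chimeranet

Chimera states, partial synchronization and disorder on a two-layer
FitzHugh–Nagumo brain-network model.

Networks of *identical* oscillators can split into coexisting coherent and
incoherent subpopulations — chimera states — a phenomenon used to explain
unihemispheric sleep (one hemisphere synchronized, the other not) and the
human first-night effect.  `chimeranet` implements a minimal brain-network
model of this kind: two intra-connected layers of FitzHugh–Nagumo (FHN)
neurons standing for the cortical hemispheres, joined by sparse inter-layer
links standing for the corpus callosum.  It is aimed at researchers in
nonlinear dynamics and network neuroscience who want reproducible phase
diagrams of synchronization regimes over the coupling parameters and the
network topology.

Node `i` of layer A evolves as (layer B mirrored)

    eps du_i/dt = u_i - u_i^3/3 - v_i
                  + (lambda_in /k_in,i)  Σ_j A_ij  [D (x_j - x_i)]_u
                  + (lambda_out/k_out,i) Σ_j AB_ij [D (x_j^b - x_i)]_u
       dv_i/dt = u_i + a + (analogous terms with [·]_v)

with `x = (u, v)`, eps = 0.05, a = 0.5 (oscillatory regime), and the
rotational coupling matrix `D(alpha) = [[cos a, sin a], [-sin a, cos a]]`.
Diagnostics are the per-node mean phase velocity `omega_i = 2 pi M_i / DT`
(`M_i` = spike count), read over the omega-sorted index, and the spatial
coherence `g0(t)` / its time average `g1`, which classify each layer as
synchronized (g1 > 0.95), disordered (g1 < 0.05) or partially synchronized.
The package also ships the synthetic two-layer generator (Erdos–Renyi
subnetworks rewired by degree-preserving swaps to clustering C = 0.7, plus
uniformly random inter-layer links), parameter-plane sweep orchestration,
and the analytic synchronization borderline
`lambda_out(alpha) = y / (cos(alpha) du + sin(alpha) dv) - lambda_in`.

## Worked example

Generate a two-layer modular network, run the four canonical coupling
scenarios, and inspect the diagnostics:

```python
import numpy as np
from chimeranet import (
    FHNParameters, RunConfig, add_interlayer_links,
    generate_modular_subnetwork, regime_showcase, omega_plateau_fraction,
)

adj_a = generate_modular_subnetwork(200, 10, 0.7, seed=42)   # C = 0.7
adj_b = generate_modular_subnetwork(200, 10, 0.7, seed=43)
net = add_interlayer_links(adj_a, adj_b, 100, seed=7)        # 100 callosal links

config = RunConfig(t_trans=500.0, t_measure=1000.0, seed=3)
for scenario in ("disorder", "chimera", "unihemispheric", "sync"):
    s = regime_showcase(net, scenario, config)
    print(f"{scenario:14s} g1_a={s.g1_a:.3f} ({s.label_a}), "
          f"g1_b={s.g1_b:.3f} ({s.label_b}), "
          f"plateau={omega_plateau_fraction(s.omega_a_sorted):.2f}")
```

Output (exact, given these seeds):

```
disorder       g1_a=0.075 (partial), g1_b=0.075 (partial), plateau=0.01
chimera        g1_a=0.104 (partial), g1_b=0.104 (partial), plateau=0.02
unihemispheric g1_a=0.228 (partial), g1_b=0.228 (partial), plateau=0.01
sync           g1_a=1.000 (synchronized), g1_b=1.000 (synchronized), plateau=1.00
```

Reading: at strong coupling (`sync`: lambda_in = 4.0, lambda_out = 3.5) both
layers lock completely — g1 = 1 and every node shares one frequency
(plateau = 1.00).  At weak coupling (`disorder`: 0.1/0.3) coherence sits
near the measure's noise floor.  The intermediate scenarios land in the
partial band (0.05 < g1 < 0.95); on this sparse synthetic network
(l_out = 100, so most nodes carry no inter-layer link) the chimera-scenario
couplings produce a low-coherence partial state rather than the broad
frequency plateau they produce on a densely bridged cortical connectome —
see `docs/methods.md` for why regime locations shift with topology.

The same pipeline is scriptable from the shell:

```bash
chimeranet gen-network --n 200 --mean-degree 10 --c-target 0.7 \
    --l-out 100 --seed 1 --out net
chimeranet net-stats --prefix net
chimeranet showcase --scenario sync --prefix net --seed 3
chimeranet borderline --y 1.0,1.5,2.0 --out curves.csv
```

A real connectome can be loaded from a TSV edge list plus a node→hemisphere
map via `load_layered_edge_list` / `remove_isolated_nodes` (isolated ROIs
are dropped, original labels retained).

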