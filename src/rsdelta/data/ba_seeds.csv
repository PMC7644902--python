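# Synthetic Brodmann-area seed directions on a template cortical sphere.
# One row per BA: unit direction of the area's centroid on the right
# hemisphere (x right, y anterior, z up); the left hemisphere is the
# x-mirror. Voxels are labeled by their nearest seed (spherical Voronoi).
# This is a desk-scale stand-in for a voxelwise cytoarchitectonic atlas.
ba,roi,x,y,z
8,frontal,0.28,0.62,0.68
9,frontal,0.32,0.78,0.48
10,frontal,0.22,0.95,0.10
11,frontal,0.22,0.85,-0.40
44,frontal,0.80,0.45,0.15
45,frontal,0.78,0.55,-0.05
46,frontal,0.62,0.70,0.25
47,frontal,0.68,0.60,-0.30
1,central,0.42,0.00,0.88
2,central,0.45,-0.08,0.86
3,central,0.40,0.05,0.90
4,central,0.35,0.12,0.92
6,central,0.30,0.35,0.88
5,parietal,0.25,-0.30,0.92
7,parietal,0.22,-0.52,0.82
30,parietal,0.12,-0.68,0.32
39,parietal,0.65,-0.60,0.42
40,parietal,0.72,-0.40,0.52
43,parietal,0.85,-0.05,0.25
17,occipital,0.10,-0.97,-0.05
18,occipital,0.28,-0.93,0.05
19,occipital,0.48,-0.84,0.15
20,temporal,0.85,0.05,-0.52
21,temporal,0.95,-0.10,-0.28
22,temporal,0.95,-0.20,-0.02
37,temporal,0.80,-0.50,-0.28
38,temporal,0.82,0.45,-0.35
41,temporal,0.90,-0.15,0.12
42,temporal,0.93,-0.05,0.08
23,none,0.06,-0.42,0.55
24,none,0.06,0.45,0.60
31,none,0.08,-0.55,0.68
32,none,0.08,0.60,0.45
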