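# Species thermophysical parameter table: per-section geometry and
# species-level calibration constants (wm = water-loss-rate parameter,
# p1..p3 = radial moisture-profile fractions). Density in g/cm^3 (oven dry),
# moisture in percent of dry mass.
species,tree,section,diameter_mm,bark_thickness_mm,moisture_pct,density_g_cm3,wm,p1,p2,p3
Acer rubrum,1,1,140,2.84,80.63,0.523,0.8,1,0.5,0.2
Acer rubrum,1,2,131,3.5,80.63,0.523,0.8,1,0.5,0.2
Acer rubrum,2,1,125,3,69.97,0.629,0.8,1,0.5,0.2
Acer rubrum,2,2,122,3,69.97,0.629,0.8,1,0.5,0.2
Acer rubrum,3,1,136,4,67.89,0.613,0.8,1,0.5,0.2
Acer rubrum,3,2,128,3.9,67.89,0.613,0.8,1,0.5,0.2
Acer saccharum,4,1,140,3.7,45.3,0.63,1,1,0.5,0.2
Acer saccharum,4,2,120,3,45.3,0.63,1,1,0.5,0.2
Acer saccharum,4,3,126,3,45.3,0.63,1,1,0.5,0.2
Acer saccharum,5,1,128,3,49.21,0.662,1,1,0.5,0.2
Acer saccharum,5,2,126,3,49.21,0.662,1,1,0.5,0.2
Acer saccharum,6,1,133,3.4,47.14,0.677,1,1,0.5,0.2
Carya tomentosa,7,1,139,8,36.47,0.735,0.2,1,0.83,0.26
Carya tomentosa,8,1,151,10.4,36.64,0.69,0.2,1,0.83,0.26
Carya tomentosa,8,2,130,8.6,36.64,0.69,0.2,1,0.83,0.26
Carya tomentosa,9,1,140,8.54,38.04,0.731,0.2,1,0.83,0.26
Carya tomentosa,9,2,129,6.9,38.04,0.731,0.2,1,0.83,0.26
Liriodendron tulipifera,10,1,136,6.2,88.13,0.437,1,0.63,0.26,0.19
Liriodendron tulipifera,10,2,132,7,88.13,0.437,1,0.63,0.26,0.19
Liriodendron tulipifera,11,1,130,8,87.99,0.401,1,0.63,0.26,0.19
Liriodendron tulipifera,11,2,126,8,87.99,0.401,1,0.63,0.26,0.19
Liriodendron tulipifera,12,1,130,8,105.11,0.443,1,0.63,0.26,0.19
Liriodendron tulipifera,12,2,126,6,105.11,0.443,1,0.63,0.26,0.19
Nyssa sylvatica,13,1,134,6.2,57.12,0.468,0.6,1,0.5,0.2
Nyssa sylvatica,13,2,129,6.1,57.12,0.468,0.6,1,0.5,0.2
Nyssa sylvatica,14,1,132,6,51.82,0.501,0.6,1,0.5,0.2
Nyssa sylvatica,14,2,102,6,51.82,0.501,0.6,1,0.5,0.2
Nyssa sylvatica,15,1,135,5.8,44.91,0.509,0.6,1,0.5,0.2
Nyssa sylvatica,15,2,110,4,44.91,0.509,0.6,1,0.5,0.2
Pinus strobus,16,1,125,3.7,100,0.338,0.8,0.63,0.26,0.19
Pinus strobus,16,2,105,2.9,100,0.338,0.8,0.63,0.26,0.19
Pinus strobus,16,3,100,2.4,100,0.338,0.8,0.63,0.26,0.19
Pinus strobus,17,1,140,3.1,100,0.3,0.8,0.63,0.26,0.19
Pinus strobus,17,2,140,2.6,100,0.3,0.8,0.63,0.26,0.19
Pinus strobus,18,1,125,3.1,100,0.323,0.8,0.63,0.26,0.19
Pinus strobus,18,2,123,3.1,100,0.323,0.8,0.63,0.26,0.19
Quercus prinus,19,1,134,9,40.57,0.633,0.1,1,0.5,0.2
Quercus prinus,19,2,130,7,40.57,0.633,0.1,1,0.5,0.2
Quercus prinus,20,1,120,8,39.39,0.609,0.1,1,0.5,0.2
Quercus prinus,20,2,114,8,39.39,0.609,0.1,1,0.5,0.2
Quercus prinus,21,1,132,6,40.9,0.631,0.1,1,0.5,0.2
Quercus prinus,21,2,128,8,40.9,0.631,0.1,1,0.5,0.2
Quercus prinus,22,1,124,12,41.97,0.672,0.1,1,0.5,0.2
Quercus prinus,22,2,120,11,41.97,0.672,0.1,1,0.5,0.2
Quercus prinus,22,3,108,8,41.97,0.672,0.1,1,0.5,0.2
Quercus rubra,23,1,128,5.9,37.53,0.697,0.5,1,0.5,0.2
Quercus rubra,23,2,128,5,37.53,0.697,0.5,1,0.5,0.2
Quercus rubra,24,1,142,8,35.93,0.724,0.5,1,0.5,0.2
Quercus rubra,24,2,124,6,35.93,0.724,0.5,1,0.5,0.2
Quercus rubra,25,1,140,9,42.81,0.716,0.5,1,0.5,0.2
Quercus rubra,25,2,132,5,42.81,0.716,0.5,1,0.5,0.2
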