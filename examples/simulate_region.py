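"""Generate a synthetic study region and monitoring network.

Builds a 10 km x 10 km region with a 1 km modelled-background NO2 grid and
a 60-site network (52 diffusion tubes, 8 automatic monitors, 4 co-located
pairs), then draws observations from the geostatistical fusion model.
"""

import airfusion as af

cfg = af.SyntheticConfig(extent_m=(0.0, 10_000.0, 0.0, 10_000.0),
                         n_tubes=52, n_monitors=8, n_colocated=4, seed=3)
sites, grid = af.generate_dataset(cfg)

print(f"grid: {len(grid)} cells of "
      f"{cfg.grid_resolution_m / 1000:.0f} km, "
      f"{int(grid['urban'].sum())} urban / {int((~grid['urban']).sum())} rural")
print(f"modelled background NO2: urban mean "
      f"{grid.loc[grid['urban'], 'pcm_no2_ugm3'].mean():.2f} ug/m3, "
      f"rural mean {grid.loc[~grid['urban'], 'pcm_no2_ugm3'].mean():.2f} ug/m3")
print(f"sites: {len(sites)} "
      f"({(sites['source'] == 'tube').sum()} tubes, "
      f"{(sites['source'] == 'monitor').sum()} monitors)")
print("environments:", sites["environment"].value_counts().to_dict())
print(f"observed NO2: median {sites['no2_ugm3'].median():.1f} ug/m3, "
      f"range {sites['no2_ugm3'].min():.1f}-{sites['no2_ugm3'].max():.1f}")
print("\nThe urban bump makes city-centre cells roughly exp(0.9) ~ 2.5x the")
print("rural background, and sites are placed preferentially in polluted")
print("cells, mimicking compliance-driven network design.")
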