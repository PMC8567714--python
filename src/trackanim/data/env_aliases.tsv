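# Snapshot of known environmental variable names -> display alias, unit.
# Tab-separated: raw column name (case-insensitive) <TAB> alias <TAB> unit.
# Units are editable placeholders; edit or extend this file freely.
ndvi	NDVI
modis land vegetation indices 1km 16d ndvi	NDVI
tail_wind	Tail-Wind	m/s
tail wind	Tail-Wind	m/s
movebank tail wind	Tail-Wind	m/s
cross_wind	Cross-Wind	m/s
cross wind	Cross-Wind	m/s
movebank cross wind	Cross-Wind	m/s
thermal_uplift	Thermal Uplift	m/s
thermal uplift	Thermal Uplift	m/s
movebank thermal uplift	Thermal Uplift	m/s
ocean_npp	Ocean NPP	mgC m-2 d-1
ocean npp	Ocean NPP	mgC m-2 d-1
ocean productivity npp	Ocean NPP	mgC m-2 d-1
v_wind_10m	10 meter V-Wind	m/s
10m v wind	10 meter V-Wind	m/s
ecmwf interim full daily sfc-fc wind (10 m above ground v component)	10 meter V-Wind	m/s
u_wind_10m	10 meter U-Wind	m/s
10m u wind	10 meter U-Wind	m/s
temperature_2m	2 meter Temperature	K
2m temperature	2 meter Temperature	K
ecmwf interim full daily sfc temperature (2 m above ground)	2 meter Temperature	K
wind_direction	Wind Direction	deg
wind direction	Wind Direction	deg
computed_speed	Computed Speed	m/s
move_azimuth	Move Azimuth	deg
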