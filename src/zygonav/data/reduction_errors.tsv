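site	displacement_mm	rot_x_deg	rot_y_deg	rot_z_deg
1	0.905	0.505	0.415	-0.139
2	0.375	-0.679	1.433	-0.869
3	1.117	0.038	0.969	1.133
4	0.263	1.858	0.243	1.356
5	1.137	0.124	0.139	-0.342
6	1.225	-0.807	-1.47	-0.951
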