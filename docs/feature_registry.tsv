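index	feature	category
0	spike_rate	general_activity
1	spike_rate_sd	oscillation
2	spike_rate_cvtime	oscillation
3	spike_rate_cvnet	synchronization
4	tonic_spike_rate	general_activity
5	tonic_spike_rate_sd	oscillation
6	tonic_spike_rate_cvtime	oscillation
7	tonic_spike_rate_cvnet	synchronization
8	burst_spike_fraction	general_activity
9	burst_spike_fraction_sd	oscillation
10	burst_spike_fraction_cvtime	oscillation
11	burst_spike_fraction_cvnet	synchronization
12	spike_contrast	general_activity
13	spike_contrast_sd	oscillation
14	spike_contrast_cvtime	oscillation
15	spike_contrast_cvnet	synchronization
16	fano_factor	general_activity
17	fano_factor_sd	oscillation
18	fano_factor_cvtime	oscillation
19	fano_factor_cvnet	synchronization
20	isi_mean	general_activity
21	isi_mean_sd	oscillation
22	isi_mean_cvtime	oscillation
23	isi_mean_cvnet	synchronization
24	isi_median	general_activity
25	isi_median_sd	oscillation
26	isi_median_cvtime	oscillation
27	isi_median_cvnet	synchronization
28	isi_cv	general_activity
29	isi_cv_sd	oscillation
30	isi_cv_cvtime	oscillation
31	isi_cv_cvnet	synchronization
32	isi_p10	general_activity
33	isi_p10_sd	oscillation
34	isi_p10_cvtime	oscillation
35	isi_p10_cvnet	synchronization
36	isi_p90	general_activity
37	isi_p90_sd	oscillation
38	isi_p90_cvtime	oscillation
39	isi_p90_cvnet	synchronization
40	log_isi_mean	general_activity
41	log_isi_mean_sd	oscillation
42	log_isi_mean_cvtime	oscillation
43	log_isi_mean_cvnet	synchronization
44	log_isi_sd	general_activity
45	log_isi_sd_sd	oscillation
46	log_isi_sd_cvtime	oscillation
47	log_isi_sd_cvnet	synchronization
48	burst_rate	general_activity
49	burst_rate_sd	oscillation
50	burst_rate_cvtime	oscillation
51	burst_rate_cvnet	synchronization
52	burst_period	general_activity
53	burst_period_sd	oscillation
54	burst_period_cvtime	oscillation
55	burst_period_cvnet	synchronization
56	burst_period_median	general_activity
57	burst_period_median_sd	oscillation
58	burst_period_median_cvtime	oscillation
59	burst_period_median_cvnet	synchronization
60	burst_period_cv	general_activity
61	burst_period_cv_sd	oscillation
62	burst_period_cv_cvtime	oscillation
63	burst_period_cv_cvnet	synchronization
64	burst_period_min	general_activity
65	burst_period_min_sd	oscillation
66	burst_period_min_cvtime	oscillation
67	burst_period_min_cvnet	synchronization
68	burst_period_max	general_activity
69	burst_period_max_sd	oscillation
70	burst_period_max_cvtime	oscillation
71	burst_period_max_cvnet	synchronization
72	burst_duty_fraction	general_activity
73	burst_duty_fraction_sd	oscillation
74	burst_duty_fraction_cvtime	oscillation
75	burst_duty_fraction_cvnet	synchronization
76	burst_duration	burst_structure
77	burst_duration_sd	oscillation
78	burst_duration_cvtime	oscillation
79	burst_duration_cvnet	synchronization
80	burst_duration_median	burst_structure
81	burst_duration_median_sd	oscillation
82	burst_duration_median_cvtime	oscillation
83	burst_duration_median_cvnet	synchronization
84	burst_duration_cv	burst_structure
85	burst_duration_cv_sd	oscillation
86	burst_duration_cv_cvtime	oscillation
87	burst_duration_cv_cvnet	synchronization
88	burst_duration_min	burst_structure
89	burst_duration_min_sd	oscillation
90	burst_duration_min_cvtime	oscillation
91	burst_duration_min_cvnet	synchronization
92	burst_duration_max	burst_structure
93	burst_duration_max_sd	oscillation
94	burst_duration_max_cvtime	oscillation
95	burst_duration_max_cvnet	synchronization
96	spikes_in_burst	burst_structure
97	spikes_in_burst_sd	oscillation
98	spikes_in_burst_cvtime	oscillation
99	spikes_in_burst_cvnet	synchronization
100	spikes_in_burst_median	burst_structure
101	spikes_in_burst_median_sd	oscillation
102	spikes_in_burst_median_cvtime	oscillation
103	spikes_in_burst_median_cvnet	synchronization
104	spikes_in_burst_cv	burst_structure
105	spikes_in_burst_cv_sd	oscillation
106	spikes_in_burst_cv_cvtime	oscillation
107	spikes_in_burst_cv_cvnet	synchronization
108	spikes_in_burst_min	burst_structure
109	spikes_in_burst_min_sd	oscillation
110	spikes_in_burst_min_cvtime	oscillation
111	spikes_in_burst_min_cvnet	synchronization
112	spikes_in_burst_max	burst_structure
113	spikes_in_burst_max_sd	oscillation
114	spikes_in_burst_max_cvtime	oscillation
115	spikes_in_burst_max_cvnet	synchronization
116	burst_spike_density	burst_structure
117	burst_spike_density_sd	oscillation
118	burst_spike_density_cvtime	oscillation
119	burst_spike_density_cvnet	synchronization
120	burst_spike_density_median	burst_structure
121	burst_spike_density_median_sd	oscillation
122	burst_spike_density_median_cvtime	oscillation
123	burst_spike_density_median_cvnet	synchronization
124	burst_spike_density_cv	burst_structure
125	burst_spike_density_cv_sd	oscillation
126	burst_spike_density_cv_cvtime	oscillation
127	burst_spike_density_cv_cvnet	synchronization
128	burst_spike_rate	burst_structure
129	burst_spike_rate_sd	oscillation
130	burst_spike_rate_cvtime	oscillation
131	burst_spike_rate_cvnet	synchronization
132	burst_spike_rate_median	burst_structure
133	burst_spike_rate_median_sd	oscillation
134	burst_spike_rate_median_cvtime	oscillation
135	burst_spike_rate_median_cvnet	synchronization
136	burst_spike_rate_cv	burst_structure
137	burst_spike_rate_cv_sd	oscillation
138	burst_spike_rate_cv_cvtime	oscillation
139	burst_spike_rate_cv_cvnet	synchronization
140	intra_burst_isi	burst_structure
141	intra_burst_isi_sd	oscillation
142	intra_burst_isi_cvtime	oscillation
143	intra_burst_isi_cvnet	synchronization
144	intra_burst_isi_median	burst_structure
145	intra_burst_isi_median_sd	oscillation
146	intra_burst_isi_median_cvtime	oscillation
147	intra_burst_isi_median_cvnet	synchronization
148	intra_burst_isi_cv	burst_structure
149	intra_burst_isi_cv_sd	oscillation
150	intra_burst_isi_cv_cvtime	oscillation
151	intra_burst_isi_cv_cvnet	synchronization
152	intra_burst_isi_min	burst_structure
153	intra_burst_isi_min_sd	oscillation
154	intra_burst_isi_min_cvtime	oscillation
155	intra_burst_isi_min_cvnet	synchronization
156	intra_burst_isi_max	burst_structure
157	intra_burst_isi_max_sd	oscillation
158	intra_burst_isi_max_cvtime	oscillation
159	intra_burst_isi_max_cvnet	synchronization
160	burst_onset_isi	burst_structure
161	burst_onset_isi_sd	oscillation
162	burst_onset_isi_cvtime	oscillation
163	burst_onset_isi_cvnet	synchronization
164	burst_offset_isi	burst_structure
165	burst_offset_isi_sd	oscillation
166	burst_offset_isi_cvtime	oscillation
167	burst_offset_isi_cvnet	synchronization
168	burst_isi_trend	burst_structure
169	burst_isi_trend_sd	oscillation
170	burst_isi_trend_cvtime	oscillation
171	burst_isi_trend_cvnet	synchronization
172	burst_symmetry	burst_structure
173	burst_symmetry_sd	oscillation
174	burst_symmetry_cvtime	oscillation
175	burst_symmetry_cvnet	synchronization
176	burst_amplitude	burst_structure
177	burst_amplitude_cvnet	synchronization
178	burst_area	burst_structure
179	burst_area_cvnet	synchronization
180	burst_plateau	burst_structure
181	burst_plateau_cvnet	synchronization
182	burst_rise_time	burst_structure
183	burst_rise_time_cvnet	synchronization
184	burst_half_width	burst_structure
185	burst_half_width_cvnet	synchronization
186	burst_profile_duration	burst_structure
187	burst_profile_duration_cvnet	synchronization
188	burst_profile_skew	burst_structure
189	burst_profile_skew_cvnet	synchronization
190	burst_peak_mean_ratio	burst_structure
191	burst_peak_mean_ratio_cvnet	synchronization
192	syn_all	synchronization
193	syn_share	synchronization
194	event_rate	synchronization
195	hamming_factor	synchronization
196	pop_burst_rate	synchronization
197	pop_burst_duration	synchronization
198	pop_burst_duration_cv	synchronization
199	pop_burst_spikes	synchronization
200	pop_burst_period	synchronization
201	pop_burst_period_cv	synchronization
202	pop_burst_participation_cv	synchronization
203	active_unit_fraction	general_activity
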