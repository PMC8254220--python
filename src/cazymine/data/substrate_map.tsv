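# Default CAZy family -> polysaccharide-degradation category assignments.
# The GH5 and GH3 rows follow the published multi-substrate assignments for
# these poly-specific families; the remaining rows are canonical activities
# from the CAZy literature. Subfamilies inherit their base-family row unless
# listed explicitly. Replace with your own TSV to change the scheme.
# CBM families are deliberately absent (non-catalytic).
family	categories
GH5	cellulose,mannan,xylan,xyloglucan
GH3	beta-glucan,cellulose,xylan,xyloglucan
GH1	beta-glucan,cellulose
GH6	cellulose
GH7	cellulose
GH9	cellulose
GH12	cellulose,xyloglucan
GH45	cellulose
AA9	cellulose
GH10	xylan
GH11	xylan
GH30	xylan
GH43	xylan
GH51	xylan
GH62	xylan
GH67	xylan
GH115	xylan
CE1	xylan
CE4	chitin,xylan
CE5	xylan
CE15	xylan
GH16	beta-glucan
GH17	beta-glucan
GH55	beta-glucan
GH64	beta-glucan
GH81	beta-glucan
GH18	chitin
GH19	chitin
GH20	chitin
AA1	lignin
AA2	lignin
GH2	mannan
GH26	mannan
GH27	mannan
GH36	mannan
GH38	mannan
GH76	mannan
GH92	mannan
GH113	mannan
GH28	pectin
GH78	pectin
GH88	pectin
GH105	pectin
PL1	pectin
PL3	pectin
PL4	pectin
PL9	pectin
CE8	pectin
CE12	pectin
GH13	starch
GH14	starch
GH15	starch
GH31	starch
GH97	starch
GH29	xyloglucan
GH74	xyloglucan
GH95	xyloglucan
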