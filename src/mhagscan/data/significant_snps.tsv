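# Curated table of SNP loci at which donor-recipient mismatches are significantly
# associated with corneal graft rejection (57 SNPs) or acceptance (4 SNPs) in a
# three-line semi-inbred swine corneal-transplant cohort.
# Coordinates: Sscrofa 10.2 (Ensembl release 83); chromosome/position "0" = unknown.
# position_bp_alt holds the second value where two positions were reported for one locus.
# alt_chromosome records a differing chromosome assignment in the older Sscrofa 9 assembly.
chromosome	position_bp	position_bp_alt	model1	model2	direction	alt_chromosome
1	132826911	0	0	1	rejection
1	133258994	0	0	1	rejection
1	133099036	0	0	1	rejection
1	133084921	0	0	1	rejection
1	133326538	0	0	1	rejection
1	133472365	0	0	1	rejection
1	134378501	0	0	1	rejection
1	134796719	0	0	1	rejection
1	135375075	0	0	1	rejection
1	0	0	0	1	rejection
1	0	0	0	1	rejection
1	135569814	0	0	1	rejection
1	135930910	136076989	0	1	rejection
1	136240599	0	0	1	rejection
1	136427159	0	0	1	rejection
1	136639460	0	0	1	rejection
1	136780600	0	0	1	rejection
1	137134551	0	0	1	rejection
1	137512402	0	0	1	rejection
1	137887750	0	0	1	rejection
1	138686941	0	0	1	rejection
1	139295346	0	0	1	rejection
1	140022043	140141190	0	1	rejection
1	140052792	140172769	0	1	rejection
1	0	0	0	1	rejection
7	29490937	0	0	1	rejection	1
1	142944521	0	0	1	rejection
1	142970565	0	0	1	rejection
1	143601266	0	0	1	rejection
1	144487578	0	0	1	rejection
1	144865731	0	0	1	rejection
1	144888036	0	0	1	rejection
1	145285984	0	0	1	rejection
1	145605557	0	0	1	rejection
1	145711971	0	0	1	rejection
1	137462211	0	0	1	rejection
1	146247253	0	0	1	rejection
4	9649533	0	1	0	rejection
4	9885672	0	1	0	rejection
4	10283814	0	1	0	rejection
4	10331873	0	1	0	rejection
4	10355258	0	1	0	rejection
4	10423196	0	1	0	rejection
4	83279186	0	1	1	rejection
6	10893273	0	0	1	rejection
6	10937617	0	0	1	rejection
6	11003757	0	0	1	rejection
6	13664912	0	0	1	rejection
9	9183235	0	1	0	rejection
9	11133568	0	1	0	rejection
9	11355126	0	1	0	rejection
9	11394193	0	1	0	rejection
9	0	0	1	0	rejection
9	11670612	0	1	0	rejection
9	11819832	0	1	0	rejection
14	1404225	0	0	1	rejection
0	0	0	1	1	rejection
4	19490147	0	0	1	acceptance
4	19517211	0	0	1	acceptance
4	19917508	0	0	1	acceptance
18	11099460	0	1	0	acceptance
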