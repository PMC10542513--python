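idx	X	Y
1	0.012125694023769843	0.30426244357013982
1	12.007423536264922	-0.14559746681779431
2	12.007421819392841	-0.14559737129998823
2	21.002176874204235	-0.50342653448932673
3	21.00216748460242	-0.50342639537457357
3	31.004289413836755	-0.58341485871209842
4	31.004277701507995	-0.58341507755034405
4	43.002408488062095	-0.16658395078356883
5	43.002395719166493	-0.16658437963768361
5	52.005507945824839	0.014879803963135351
6	52.005465999327157	0.014878000261199393
6	62.003880207439352	0.42273308727411912
7	62.003870352800568	0.42273215434406541
7	73.022407352588772	0.7444153906341362
8	73.022492129486764	0.74439722067449909
8	78.983077209070586	-0.19428968129861354
9	78.982981712642228	-0.19430593343758726
9	82.986693635792605	-0.041883162392994444
10	82.986537286475894	-0.041888518484295888
10	88.995532966411787	-0.11468150133306623
11	88.99545791961971	-0.11468294541980487
11	94.989114897603471	0.26447456260182362
12	94.989089552070354	0.26447267652667888
12	105.98320410178438	-0.15388943045639214
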