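# Colour scale catalog: one scale per non-comment line.
# Columns (tab-separated): id, name, comma-separated low:high:#rrggbb bins.
# Bins are integer-inclusive density percent ranges and must cover 0-100
# with no gaps or overlaps. Edit or replace via --scales_file.
1	deciles blue-red	0:9:#0000ff,10:19:#1c00e3,20:29:#3900c6,30:39:#5500aa,40:49:#71008e,50:59:#8e0071,60:69:#aa0055,70:79:#c60039,80:89:#e3001c,90:100:#ff0000
2	deciles white-blue	0:9:#ffffff,10:19:#e3e3f2,20:29:#c6c6e5,30:39:#aaaad8,40:49:#8e8ecb,50:59:#7171bf,60:69:#5555b2,70:79:#3939a5,80:89:#1c1c98,90:100:#00008b
3	deciles white-red	0:9:#ffffff,10:19:#f2e3e3,20:29:#e5c6c6,30:39:#d8aaaa,40:49:#cb8e8e,50:59:#bf7171,60:69:#b25555,70:79:#a53939,80:89:#981c1c,90:100:#8b0000
4	deciles green-red	0:9:#008000,10:19:#1c7200,20:29:#396400,30:39:#555500,40:49:#714700,50:59:#8e3900,60:69:#aa2b00,70:79:#c61c00,80:89:#e30e00,90:100:#ff0000
5	deciles greyscale	0:9:#f5f5f5,10:19:#dadada,20:29:#bfbfbf,30:39:#a3a3a3,40:49:#888888,50:59:#6d6d6d,60:69:#525252,70:79:#363636,80:89:#1b1b1b,90:100:#000000
6	deciles yellow-red	0:9:#ffff00,10:19:#f2e300,20:29:#e5c600,30:39:#d8aa00,40:49:#cb8e00,50:59:#bf7100,60:69:#b25500,70:79:#a53900,80:89:#981c00,90:100:#8b0000
7	deciles cyan-magenta	0:9:#00ffff,10:19:#1ce3ff,20:29:#39c6ff,30:39:#55aaff,40:49:#718eff,50:59:#8e71ff,60:69:#aa55ff,70:79:#c639ff,80:89:#e31cff,90:100:#ff00ff
8	quartiles blue-red	0:24:#0000ff,25:49:#5500aa,50:74:#aa0055,75:100:#ff0000
9	quintiles green-red	0:19:#008000,20:39:#406000,40:59:#804000,60:79:#bf2000,80:100:#ff0000
10	low-density blue-red	0:0:#bebebe,1:1:#0000ff,2:2:#2000df,3:3:#4000bf,4:4:#60009f,5:5:#800080,6:6:#9f0060,7:7:#bf0040,8:8:#df0020,9:9:#ff0000,10:100:#8b0000
11	low-density green-red	0:0:#bebebe,1:1:#008000,2:2:#207000,3:3:#406000,4:4:#605000,5:5:#804000,6:6:#9f3000,7:7:#bf2000,8:8:#df1000,9:9:#ff0000,10:100:#8b0000
12	gc-content	0:29:#bebebe,30:30:#008000,31:31:#0d7900,32:32:#1b7300,33:33:#286c00,34:34:#366500,35:35:#435e00,36:36:#515800,37:37:#5e5100,38:38:#6b4a00,39:39:#794300,40:40:#863d00,41:41:#943600,42:42:#a12f00,43:43:#ae2800,44:44:#bc2200,45:45:#c91b00,46:46:#d71400,47:47:#e40d00,48:48:#f20700,49:49:#ff0000,50:100:#8b0000
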